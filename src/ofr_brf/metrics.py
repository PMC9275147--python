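"""Model-free center-surround indices extracted from summation curves.

These indices characterise the behavioral receptive field directly from the
measured points, with no fitting or interpolation — each is set by the tested
data point closest to its amplitude criterion:

* GSA (grating summation area): smallest disk diameter reaching at least 95%
  of the maximal response R_opt; a proxy for the excitatory center extent.
* SExt (surround extent): smallest diameter at or beyond the GSA whose
  response is within 5% of the asymptote R_asy (response at the largest
  diameter); a proxy for the inhibitory field extent.
* SSI (surround suppression index): (R_opt - R_asy) / R_opt, the fractional
  response loss from optimal to very large stimuli.
* AMD (annular minimal diameter): on ring curves, the first inner diameter
  whose response reaches within 5% of the floor R_min observed with the most
  occluded center. An alternative criterion (5% of the ring peak) is
  available via ``criterion='peak'``.

All indices are invariant under positive rescaling of the amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import defaults as d
from .traces import SummationCurve

__all__ = [
    "ModelFreeIndices",
    "grating_summation_area",
    "surround_extent",
    "suppression_index",
    "annular_minimal_diameter",
    "model_free_indices",
    "index_time_course",
]


@dataclass
class ModelFreeIndices:
    """Indices for one curve (and, for AMD, its paired ring curve)."""

    gsa: float
    sext: float
    ssi: float
    r_opt: float
    r_asy: float
    window: tuple[float, float]
    amd: float = math.nan
    flags: tuple[str, ...] = ()


def grating_summation_area(curve: SummationCurve,
                           criterion: float = d.GSA_CRITERION) -> float:
    """Smallest tested diameter whose amplitude reaches ``criterion`` of the
    curve maximum."""
    _require(curve, "disk")
    r_opt = curve.amp.max()
    hit = curve.amp >= criterion * r_opt
    return float(curve.diameters[np.argmax(hit)])


def surround_extent(curve: SummationCurve, gsa: float | None = None,
                    criterion: float = d.SEXT_CRITERION) -> float:
    """Smallest diameter at/beyond the GSA within ``criterion`` of the
    largest-diameter asymptote; NaN (flagged upstream) if that asymptote
    is zero."""
    _require(curve, "disk")
    r_asy = curve.amp[-1]
    if r_asy == 0:
        return math.nan
    if gsa is None:
        gsa = grating_summation_area(curve)
    ok = (curve.diameters >= gsa) & (np.abs(curve.amp - r_asy)
                                     <= criterion * abs(r_asy))
    if not ok.any():
        return math.nan
    return float(curve.diameters[np.argmax(ok)])


def suppression_index(curve: SummationCurve) -> float:
    """(R_opt - R_asy) / R_opt; NaN when R_opt is not positive."""
    _require(curve, "disk")
    r_opt = curve.amp.max()
    if r_opt <= 0:
        return math.nan
    return float((r_opt - curve.amp[-1]) / r_opt)


def annular_minimal_diameter(curve: SummationCurve,
                             criterion: float = d.AMD_CRITERION,
                             mode: str = "floor") -> float:
    """First inner diameter whose response reaches the decayed level.

    ``mode='floor'`` (default): within ``criterion`` above the floor
    R_min = amp at the largest inner diameter, i.e. amp <= (1 + criterion)
    R_min. ``mode='peak'``: first diameter with amp <= criterion * max(amp).
    A ring curve whose floor is not at the largest inner diameter (response
    not decaying) returns NaN.
    """
    if curve.shape not in ("ring", "annulus_mask"):
        raise ValueError("AMD is defined on ring curves")
    if curve.amp[-1] > curve.amp.min() + 1e-12 * max(curve.amp.max(), 1.0):
        return math.nan
    if mode == "floor":
        level = (1.0 + criterion) * curve.amp[-1]
    elif mode == "peak":
        level = criterion * curve.amp.max()
    else:
        raise ValueError("mode must be 'floor' or 'peak'")
    ok = curve.amp <= level
    if not ok.any():
        return math.nan
    return float(curve.diameters[np.argmax(ok)])


def model_free_indices(disk_curve: SummationCurve,
                       ring_curve: SummationCurve | None = None,
                       amd_mode: str = "floor") -> ModelFreeIndices:
    """All indices for one (direction, SF, speed) cell."""
    gsa = grating_summation_area(disk_curve)
    sext = surround_extent(disk_curve, gsa)
    ssi = suppression_index(disk_curve)
    flags = []
    if math.isnan(sext):
        flags.append("sext_undefined")
    if math.isnan(ssi):
        flags.append("ssi_undefined")
    amd = math.nan
    if ring_curve is not None:
        amd = annular_minimal_diameter(ring_curve, mode=amd_mode)
        if math.isnan(amd):
            flags.append("amd_undefined")
    return ModelFreeIndices(gsa=gsa, sext=sext, ssi=ssi,
                            r_opt=float(disk_curve.amp.max()),
                            r_asy=float(disk_curve.amp[-1]),
                            window=disk_curve.window, amd=amd,
                            flags=tuple(flags))


def index_time_course(indices_by_window: dict[tuple[float, float],
                                              list[ModelFreeIndices]],
                      ) -> dict[str, dict[str, float]]:
    """Linear trend of each index against analysis-window midpoint.

    ``indices_by_window`` maps a window to the per-replicate (dataset,
    direction) indices measured in it. Returns, per index, the OLS slope,
    intercept, r^2, residual df, and two-sided p across all replicates; a
    degenerate (constant) index is flagged with r^2 = 0.
    """
    if len(indices_by_window) < 2:
        raise ValueError("need at least 2 windows for a time course")
    out: dict[str, dict[str, float]] = {}
    for name in ("gsa", "sext", "ssi", "amd"):
        ts, ys = [], []
        for window, reps in indices_by_window.items():
            mid = 0.5 * (window[0] + window[1])
            for rep in reps:
                val = getattr(rep, name)
                if not math.isnan(val):
                    ts.append(mid)
                    ys.append(val)
        if len(set(ts)) < 2:
            continue
        ts_a, ys_a = np.array(ts), np.array(ys)
        if np.ptp(ys_a) == 0:
            out[name] = {"slope": 0.0, "intercept": float(ys_a[0]), "r2": 0.0,
                         "df": len(ys_a) - 2, "p": math.nan, "degenerate": True}
            continue
        res = stats.linregress(ts_a, ys_a)
        out[name] = {"slope": float(res.slope), "intercept": float(res.intercept),
                     "r2": float(res.rvalue**2), "df": len(ys_a) - 2,
                     "p": float(res.pvalue), "degenerate": False}
    return out


def _require(curve: SummationCurve, shape: str) -> None:
    if curve.shape != shape:
        raise ValueError(f"index defined on {shape} curves, got {curve.shape!r}")
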