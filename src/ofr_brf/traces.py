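"""Raw-trace processing: trial rejection, blank subtraction, windowed
amplitude measures, differentiation, and summation-curve construction.

Response amplitude is the change in horizontal eye position over short
(10 or 20 ms) windows inside the open-loop period (60-120 ms after stimulus
onset), with the mean blank-trial position change over the same window
subtracted to remove slow fixation drift. Both motion directions are
processed separately and amplitudes are reported as unsigned magnitude along
the stimulus direction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from . import defaults as d
from .synthetic import EyeTrace, Session

__all__ = [
    "VelocityProfile",
    "AmplitudeMeasure",
    "SummationCurve",
    "reject_trials",
    "mean_blank_profile",
    "position_change",
    "velocity_and_acceleration",
    "first_acceleration_peak",
    "build_summation_curve",
    "merge_small_diameter_curve",
    "curves_to_frame",
    "frame_to_curves",
]


@dataclass
class VelocityProfile:
    """Across-trial mean eye velocity (deg/s) on the 1 ms grid."""

    t: np.ndarray
    v: np.ndarray
    se: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.v) == len(self.se)):
            raise ValueError("profile arrays must share a length")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class AmplitudeMeasure:
    """Windowed position change: mean, SE, and trial count."""

    window: tuple[float, float]
    mean_dx: float
    se: float
    n: int


@dataclass
class SummationCurve:
    """Response amplitude (unsigned magnitude) vs stimulus size for one
    (shape, direction, sf, speed) cell and one analysis window."""

    shape: str
    diameters: np.ndarray   # outer diameter (disks) or inner diameter (rings)
    amp: np.ndarray
    se: np.ndarray
    n: np.ndarray
    window: tuple[float, float]
    sf: float
    speed: float
    direction: str

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.amp = np.asarray(self.amp, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.asarray(self.n)
        if len(self.diameters) != len(self.amp) or len(self.diameters) < 2:
            raise ValueError("need >= 2 (diameter, amplitude) points")
        if np.any(np.diff(self.diameters) <= 0):
            raise ValueError("diameters must be strictly increasing")

    def rescaled(self, factor: float) -> "SummationCurve":
        return replace(self, amp=self.amp * factor, se=self.se * factor)


# ---------------------------------------------------------------------------
# rejection and blank subtraction

def reject_trials(traces: Iterable[EyeTrace],
                  fixation_limit: float = d.FIXATION_LIMIT,
                  saccade_velocity_limit: float = d.SACCADE_VELOCITY_LIMIT,
                  ) -> tuple[list[EyeTrace], list[dict]]:
    """Drop trials breaking fixation before onset or containing a saccade.

    Fixation breaks: any pre-stimulus sample with |x| or |y| beyond
    ``fixation_limit``. Saccades: central-difference eye speed on either
    channel beyond ``saccade_velocity_limit`` during the epoch.
    Returns (kept traces, rejection log).
    """
    if fixation_limit <= 0 or saccade_velocity_limit <= 0:
        raise ValueError("limits must be positive")
    kept, log = [], []
    for tr in traces:
        pre = tr.t < 0
        if np.any(np.abs(tr.x[pre]) > fixation_limit) or \
                np.any(np.abs(tr.y[pre]) > fixation_limit):
            log.append({"trial_id": tr.trial_id, "reason": "fixation_break"})
            continue
        vx = np.gradient(tr.x, tr.t * 1e-3)
        vy = np.gradient(tr.y, tr.t * 1e-3)
        if np.max(np.hypot(vx, vy)) > saccade_velocity_limit:
            log.append({"trial_id": tr.trial_id, "reason": "saccade"})
            continue
        kept.append(tr)
    return kept, log


def mean_blank_profile(catch_traces: Sequence[EyeTrace]
                       ) -> tuple[np.ndarray, np.ndarray, VelocityProfile]:
    """Pointwise mean of catch-trial traces, time-locked to virtual onset.

    Returns (t, mean position, mean velocity profile).
    """
    catch_traces = list(catch_traces)
    if not catch_traces:
        raise ValueError(
            "no catch trials: pass blank=None explicitly to disable subtraction")
    t = catch_traces[0].t
    xs = np.vstack([tr.x for tr in catch_traces])
    mean_x = xs.mean(axis=0)
    vs = np.vstack([np.gradient(x, t * 1e-3) for x in xs])
    prof = VelocityProfile(t=t, v=vs.mean(axis=0),
                           se=vs.std(axis=0, ddof=1) / np.sqrt(len(catch_traces))
                           if len(catch_traces) > 1 else np.zeros_like(t),
                           n=len(catch_traces))
    return t, mean_x, prof


def _window_dx(t: np.ndarray, x: np.ndarray, window: tuple[float, float]) -> float:
    i0 = int(np.searchsorted(t, window[0]))
    i1 = int(np.searchsorted(t, window[1]))
    if not (0 <= i0 < len(t) and 0 <= i1 < len(t)) or window[0] >= window[1]:
        raise ValueError(f"window {window} outside trace")
    return float(x[i1] - x[i0])


def position_change(traces: Sequence[EyeTrace] | EyeTrace,
                    window: tuple[float, float],
                    blank: tuple[np.ndarray, np.ndarray] | None = None,
                    ) -> AmplitudeMeasure:
    """Across-trial mean (+SE) signed position change over ``window``, with
    the blank-mean change over the same window subtracted.

    ``blank`` is the (t, mean position) pair from :func:`mean_blank_profile`;
    pass None to skip subtraction.
    """
    if isinstance(traces, EyeTrace):
        traces = [traces]
    if not traces:
        raise ValueError("no trials")
    blank_dx = _window_dx(blank[0], blank[1], window) if blank is not None else 0.0
    dxs = np.array([_window_dx(tr.t, tr.x, window) - blank_dx for tr in traces])
    se = float(dxs.std(ddof=1) / np.sqrt(len(dxs))) if len(dxs) > 1 else 0.0
    return AmplitudeMeasure(window=tuple(window), mean_dx=float(dxs.mean()),
                            se=se, n=len(dxs))


# ---------------------------------------------------------------------------
# differentiation

def velocity_and_acceleration(t: np.ndarray, x: np.ndarray,
                              smooth: bool = False, smooth_window: int = 11,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference velocity (deg/s) and acceleration (deg/s^2) on the
    1 kHz grid; endpoints one-sided. Optional Savitzky-Golay smoothing of the
    position trace for noisy data (default off: the generator needs none and
    real recordings are already hardware low-pass filtered)."""
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    if smooth:
        x = savgol_filter(x, window_length=min(smooth_window, len(x) // 2 * 2 - 1),
                          polyorder=2)
    ts = np.asarray(t, dtype=float) * 1e-3
    v = np.gradient(x, ts)
    a = np.gradient(v, ts)
    return v, a


def first_acceleration_peak(t: np.ndarray, a: np.ndarray,
                            search_start: float = 40.0,
                            ) -> tuple[float, float, bool]:
    """First local maximum of acceleration after ``search_start`` ms.

    Ties break toward the earliest time. If no local maximum exists in the
    epoch, the global maximum is returned with ``no_local_max=True``.
    Returns (peak value, peak time ms, no_local_max flag).
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    idx = np.where(t >= search_start)[0]
    if idx.size < 3:
        raise ValueError("search window too short")
    lo = max(idx[0], 1)
    for i in range(lo, len(a) - 1):
        if a[i] >= a[i - 1] and a[i] >= a[i + 1] and (a[i] > a[i - 1] or a[i] > a[i + 1]):
            return float(a[i]), float(t[i]), False
    j = idx[np.argmax(a[idx])]
    return float(a[j]), float(t[j]), True


# ---------------------------------------------------------------------------
# summation curves

def build_summation_curve(session: Session | Sequence[EyeTrace], shape: str,
                          window: tuple[float, float],
                          blank: tuple[np.ndarray, np.ndarray] | None | str = "auto",
                          ) -> list[SummationCurve]:
    """Summation curves (one per direction x SF x speed cell) for ``shape``.

    The abscissa is the outer diameter for disks and the inner diameter for
    rings and annulus masks; amplitudes are the blank-corrected mean window
    position changes, signed into response magnitude along the stimulus
    direction. ``blank='auto'`` computes the blank mean from the session's
    catch trials (or skips subtraction when there are none).
    """
    traces = list(session.traces if isinstance(session, Session) else session)
    if blank == "auto":
        catch = [tr for tr in traces if tr.is_blank]
        blank = mean_blank_profile(catch)[:2] if catch else None
    cells: dict[tuple, dict[float, list[EyeTrace]]] = {}
    for tr in traces:
        c = tr.condition
        if c is None or c.shape != shape:
            continue
        key = (c.direction, c.sf, c.speed)
        diam = c.outer_diameter if shape == "disk" else c.inner_diameter
        cells.setdefault(key, {}).setdefault(diam, []).append(tr)
    curves = []
    for (direction, sf, speed), by_diam in sorted(cells.items()):
        if len(by_diam) < 2:
            raise ValueError(f"need >= 2 distinct diameters for {shape}")
        diams = np.array(sorted(by_diam))
        sign = 1.0 if direction == "rightward" else -1.0
        amps, ses, ns = [], [], []
        for diam in diams:
            m = position_change(by_diam[diam], window, blank)
            amps.append(sign * m.mean_dx)
            ses.append(m.se)
            ns.append(m.n)
        curves.append(SummationCurve(shape=shape, diameters=diams,
                                     amp=np.array(amps), se=np.array(ses),
                                     n=np.array(ns), window=tuple(window),
                                     sf=sf, speed=speed, direction=direction))
    return curves


def merge_small_diameter_curve(main: SummationCurve, small: SummationCurve,
                               common: float = d.MERGE_COMMON_DIAMETER,
                               ) -> SummationCurve:
    """Join a supplementary small-diameter curve onto the main curve after
    multiplicative rescaling at the shared ``common`` diameter.

    Points present in both sets keep the main curve's measurement.
    """
    def at(curve, diam):
        hit = np.isclose(curve.diameters, diam)
        if not hit.any():
            raise ValueError(f"diameter {diam} not in curve")
        return int(np.argmax(hit))

    factor = main.amp[at(main, common)] / small.amp[at(small, common)]
    small = small.rescaled(factor)
    extra = ~np.isin(np.round(small.diameters, 6), np.round(main.diameters, 6))
    diams = np.concatenate([main.diameters, small.diameters[extra]])
    order = np.argsort(diams)
    return SummationCurve(
        shape=main.shape,
        diameters=diams[order],
        amp=np.concatenate([main.amp, small.amp[extra]])[order],
        se=np.concatenate([main.se, small.se[extra]])[order],
        n=np.concatenate([main.n, small.n[extra]])[order],
        window=main.window, sf=main.sf, speed=main.speed,
        direction=main.direction)


# ---------------------------------------------------------------------------
# curve I/O

_CURVE_COLS = ["direction", "sf", "speed", "shape", "diameter",
               "window_t0", "window_t1", "mean_dx", "se", "n"]


def curves_to_frame(curves: Sequence[SummationCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i in range(len(c.diameters)):
            rows.append({"direction": c.direction, "sf": c.sf, "speed": c.speed,
                         "shape": c.shape, "diameter": c.diameters[i],
                         "window_t0": c.window[0], "window_t1": c.window[1],
                         "mean_dx": c.amp[i], "se": c.se[i], "n": int(c.n[i])})
    return pd.DataFrame(rows, columns=_CURVE_COLS)


def frame_to_curves(frame: pd.DataFrame) -> list[SummationCurve]:
    curves = []
    keys = ["direction", "sf", "speed", "shape", "window_t0", "window_t1"]
    for (direction, sf, speed, shape, t0, t1), grp in frame.groupby(keys, sort=True):
        grp = grp.sort_values("diameter")
        curves.append(SummationCurve(shape=shape,
                                     diameters=grp["diameter"].to_numpy(float),
                                     amp=grp["mean_dx"].to_numpy(float),
                                     se=grp["se"].to_numpy(float),
                                     n=grp["n"].to_numpy(int),
                                     window=(float(t0), float(t1)),
                                     sf=float(sf), speed=float(speed),
                                     direction=direction))
    return curves
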