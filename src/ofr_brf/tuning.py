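"""Spatial-frequency tuning of the behavioral receptive field.

Aggregates per-(dataset, direction) DoG fits, ring-decay fits, and model-free
indices across grating spatial frequency and quantifies:

* exponential decay of the center/surround extents (sigma_e, sigma_i) and of
  related spatial quantities with SF;
* the linear relation between sigma_i and sigma_e (the surround is roughly
  twice the center across the whole SF range);
* Gaussian SF tuning of the min-max-normalized excitatory and inhibitory
  gains, fitted in linear SF space (an additive offset is allowed so that an
  affinely normalized Gaussian is recovered exactly);
* decay of the ring size constant tau with SF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "TuningSummary",
    "summarize_across_sf",
    "fit_sf_decay",
    "gain_sf_tuning",
    "size_relation",
]

_QUANTITIES = ("sigma_e", "sigma_i", "g_e", "g_i", "tau",
               "gsa", "sext", "ssi", "amd")


@dataclass
class TuningSummary:
    """Per-SF parameter table plus the derived tuning relations."""

    per_sf: pd.DataFrame
    size_relation: dict[str, float]
    gain_tuning: dict[str, float]
    decay_fits: dict[str, dict[str, float]] = field(default_factory=dict)


def fit_sf_decay(sf, values) -> dict[str, float]:
    """Least-squares fit of ``a * exp(-sf / b) + c`` to a quantity vs SF
    (same family as the ring eccentricity decay, abscissa in cpd)."""
    sf = np.asarray(sf, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y)
    sf, y = sf[ok], y[ok]
    if sf.size < 3:
        raise ValueError("need >= 3 points")

    def residuals(theta):
        a, b, c = theta
        return a * np.exp(-sf / b) + c - y

    a0 = max(float(y[np.argmin(sf)] - y[np.argmax(sf)]), 1e-9)
    best = None
    for b0 in (0.2, 0.5, 1.5):
        try:
            res = least_squares(residuals, [a0, b0, float(min(y.min(), y[-1]))],
                                bounds=([0, 1e-6, -np.inf], [np.inf, 1e3, np.inf]),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return {"a": math.nan, "b": math.nan, "c": math.nan, "converged": False}
    a, b, c = best.x
    return {"a": float(a), "b": float(b), "c": float(c),
            "converged": bool(best.success)}


def gain_sf_tuning(sf, gains) -> tuple[float, float]:
    """Peak SF and SD (both cpd) of the Gaussian tuning of a gain series.

    Gains are min-max normalized to [0, 1] first, which makes the result
    invariant to positive rescaling; the Gaussian (with amplitude and offset
    free) is fitted in linear SF space.
    """
    sf = np.asarray(sf, dtype=float)
    g = np.asarray(gains, dtype=float)
    if sf.size < 4:
        raise ValueError("need >= 4 spatial frequencies")
    if np.any(g < 0):
        raise ValueError("gains must be non-negative")
    rng_g = g.max() - g.min()
    if rng_g == 0:
        raise ValueError("flat gain series: tuning undefined")
    gn = (g - g.min()) / rng_g

    def residuals(theta):
        a, mu, sd, c = theta
        return a * np.exp(-((sf - mu) ** 2) / (2 * sd**2)) + c - gn

    best = None
    for mu0 in (sf.min(), float(np.median(sf)), sf.max()):
        try:
            res = least_squares(residuals, [1.0, mu0, float(np.ptp(sf) / 3), 0.0],
                                bounds=([0, 1e-3, 1e-3, -2], [10, 10, 10, 2]),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("Gaussian tuning fit failed")
    _, mu, sd, _ = best.x
    return float(mu), float(sd)


def size_relation(sigma_e, sigma_i) -> dict[str, float]:
    """OLS of sigma_i on sigma_e: slope, intercept, r^2, df, two-sided p."""
    x = np.asarray(sigma_e, dtype=float)
    y = np.asarray(sigma_i, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length arrays of >= 3 extents")
    if np.ptp(x) == 0:
        return {"slope": math.nan, "intercept": math.nan, "r2": math.nan,
                "df": x.size - 2, "p": math.nan, "degenerate": True}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "df": x.size - 2,
            "p": float(res.pvalue), "degenerate": False}


def summarize_across_sf(replicates: pd.DataFrame,
                        normalize_gains_per_replicate: bool = True,
                        ) -> TuningSummary:
    """Build the tuning summary from a replicate table.

    ``replicates`` has one row per (dataset, direction, sf) with whichever of
    the columns sigma_e, sigma_i, g_e, g_i, tau, gsa, sext, ssi, amd are
    available (plus optional 'dataset'/'direction' identifiers). SF sets must
    agree across replicates. Means and SDs are taken across replicates per
    SF; ratio columns (sigma_i/sigma_e, g_i/g_e) are computed per replicate,
    then averaged.
    """
    df = replicates.copy()
    if "sf" not in df.columns:
        raise ValueError("replicate table needs an 'sf' column")
    sfs = np.array(sorted(df["sf"].unique()))
    if sfs.size < 3:
        raise ValueError("need >= 3 spatial frequencies")
    rep_keys = [k for k in ("dataset", "direction") if k in df.columns]
    if rep_keys:
        counts = df.groupby(rep_keys)["sf"].apply(lambda s: tuple(sorted(s)))
        if counts.nunique() > 1:
            raise ValueError("inconsistent SF sets across replicates")
    if {"sigma_e", "sigma_i"} <= set(df.columns):
        df["sigma_ratio"] = df["sigma_i"] / df["sigma_e"]
    if {"g_e", "g_i"} <= set(df.columns):
        df["gain_ratio"] = df["g_i"] / df["g_e"]

    cols = [c for c in (*_QUANTITIES, "sigma_ratio", "gain_ratio")
            if c in df.columns]
    grouped = df.groupby("sf")[cols]
    per_sf = grouped.mean().add_suffix("_mean").join(
        grouped.std(ddof=1).add_suffix("_sd")).reset_index().sort_values("sf")

    rel = (size_relation(df["sigma_e"], df["sigma_i"])
           if {"sigma_e", "sigma_i"} <= set(df.columns) else {})

    gain_tuning: dict[str, float] = {}
    if {"g_e", "g_i"} <= set(df.columns) and sfs.size >= 4:
        for col, peak_key, sd_key in (("g_e", "peak_sf_e", "sigma_sf_e"),
                                      ("g_i", "peak_sf_i", "sigma_sf_i")):
            if normalize_gains_per_replicate and rep_keys:
                # average the per-replicate normalized series, then fit once
                series = []
                for _, grp in df.groupby(rep_keys):
                    grp = grp.sort_values("sf")
                    g = grp[col].to_numpy(float)
                    if np.ptp(g) > 0:
                        series.append((g - g.min()) / np.ptp(g))
                gains = np.mean(series, axis=0)
            else:
                gains = per_sf.sort_values("sf")[f"{col}_mean"].to_numpy(float)
            try:
                peak, sd = gain_sf_tuning(sfs, gains)
                gain_tuning[peak_key] = peak
                gain_tuning[sd_key] = sd
            except (ValueError, RuntimeError):
                gain_tuning[peak_key] = math.nan
                gain_tuning[sd_key] = math.nan

    decay_fits: dict[str, dict[str, float]] = {}
    for col in ("sigma_e", "sigma_i", "tau", "gsa", "sext", "amd"):
        if col in df.columns and df[col].notna().sum() >= 3:
            try:
                decay_fits[col] = fit_sf_decay(df["sf"].to_numpy(float),
                                               df[col].to_numpy(float))
            except ValueError:
                continue
    return TuningSummary(per_sf=per_sf, size_relation=rel,
                         gain_tuning=gain_tuning, decay_fits=decay_fits)
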