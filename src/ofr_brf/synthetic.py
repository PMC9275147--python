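"""Synthetic ocular-following datasets with the statistical structure the
analysis assumes.

The generator stands in for monkey eye-coil recordings: per-trial 1 kHz
horizontal/vertical eye-position traces with a ~55 ms response latency,
amplitudes governed by a DoG summation law for disk gratings and an
exponential eccentricity decay for ring gratings, i.i.d. Gaussian position
noise, slow drift on blank catch trials, and fully interleaved
leftward/rightward directions over the standard condition grids.

The temporal response template is a cubic smoothstep velocity rise starting
at the latency and reaching a constant-velocity plateau 40 ms later; the
trace is scaled so that the noiseless position change over the reference
85-105 ms window equals the amplitude law exactly, which makes parameter
recovery testable to machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults as d
from .models import DoGParams, ExpDecayParams, dog_summation_response, exp_decay_response

__all__ = [
    "StimulusCondition",
    "BRFTruth",
    "EyeTrace",
    "Session",
    "temporal_frequency",
    "make_condition_grid",
    "amplitude_law",
    "simulate_trial",
    "simulate_session",
    "simulate_window_amplitudes",
    "default_truth",
    "session_to_frame",
    "frame_to_session",
    "write_session",
    "read_session",
]

SHAPES = ("disk", "ring", "annulus_mask")


def temporal_frequency(sf: float, speed: float) -> float:
    """Temporal frequency (Hz) of a grating of spatial frequency ``sf`` (cpd)
    drifting at ``speed`` (deg/s); simply sf * speed."""
    if sf <= 0 or speed <= 0:
        raise ValueError("sf and speed must be positive")
    return sf * speed


@dataclass(frozen=True)
class StimulusCondition:
    """One grating stimulus: geometry, spatiotemporal content and direction."""

    shape: str
    outer_diameter: float
    inner_diameter: float
    sf: float
    speed: float
    direction: str

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.direction not in d.DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.sf <= 0 or self.speed <= 0:
            raise ValueError("sf and speed must be positive")
        if not 0 <= self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 <= inner_diameter < outer_diameter")
        if self.shape == "disk" and self.inner_diameter != 0:
            raise ValueError("disk stimuli have inner_diameter == 0")

    @property
    def tf(self) -> float:
        """Temporal frequency in Hz."""
        return temporal_frequency(self.sf, self.speed)

    @property
    def sign(self) -> float:
        """Sign convention of the horizontal response (+ rightward)."""
        return 1.0 if self.direction == "rightward" else -1.0


@dataclass(frozen=True)
class BRFTruth:
    """Ground-truth forward model of the behavioral receptive field.

    ``dog`` and ``decay`` map spatial frequency (cpd) to the disk summation
    law and ring eccentricity-decay law respectively; a condition's SF must
    match a table key. ``latency`` in ms; ``noise_sd`` in deg per sample;
    ``drift_sd`` in deg/s.
    """

    dog: Mapping[float, DoGParams]
    decay: Mapping[float, ExpDecayParams]
    latency: float = d.LATENCY_MS
    noise_sd: float = d.NOISE_SD
    drift_sd: float = d.DRIFT_SD

    def __post_init__(self) -> None:
        if self.latency <= 0:
            raise ValueError("latency must be positive")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise_sd and drift_sd must be non-negative")

    def dog_for(self, sf: float) -> DoGParams:
        return _lookup(self.dog, sf, "DoG")

    def decay_for(self, sf: float) -> ExpDecayParams:
        return _lookup(self.decay, sf, "decay")


def _lookup(table: Mapping[float, object], sf: float, what: str):
    for key, val in table.items():
        if abs(key - sf) < 1e-9:
            return val
    raise KeyError(f"no {what} truth for sf={sf}")


def default_truth(*, include_suspect: bool = False,
                  noise_sd: float = d.NOISE_SD,
                  drift_sd: float = d.DRIFT_SD,
                  latency: float = d.LATENCY_MS) -> BRFTruth:
    """Default truth table: per-SF DoG means for disks; ring decay laws with
    the per-SF default tau, gains set so the ring response at inner diameter
    0 equals the disk asymptote (95%/5% split between g_r and r_0).

    The internally inconsistent 0.72 cpd row is excluded unless
    ``include_suspect`` is set.
    """
    dog: dict[float, DoGParams] = {}
    decay: dict[float, ExpDecayParams] = {}
    for sf, (s_e, s_i, g_e, g_i) in d.DOG_TABLE.items():
        if sf in d.SUSPECT_SFS and not include_suspect:
            continue
        dog[sf] = DoGParams(sigma_e=s_e, sigma_i=s_i, g_e=g_e, g_i=g_i)
        base = max(g_e - g_i, 0.0)
        decay[sf] = ExpDecayParams(g_r=0.95 * base, tau=d.tau_default(sf),
                                   r_0=0.05 * base)
    return BRFTruth(dog=dog, decay=decay, latency=latency,
                    noise_sd=noise_sd, drift_sd=drift_sd)


# ---------------------------------------------------------------------------
# condition grids

def make_condition_grid(experiment_id, config: dict | None = None) -> list[StimulusCondition]:
    """Stimulus grid for one experiment, fully crossed with both directions.

    ``1``  -- 12 disk diameters + 12 ring inner diameters at 0.36 cpd, 30 deg/s.
    ``2``  -- 12 disks at speeds {15, 30, 45} deg/s.
    ``3``  -- disks and rings at six SFs {0.12 .. 1.41} cpd, 30 deg/s.
    ``'3s'`` -- supplementary small disks (1-7.1 deg) at the three highest SFs.
    ``4``  -- annulus-mask controls: 3.4 deg wide mean-luminance ring over a
    60 deg grating, masks at the 12 eccentricities.
    """
    cfg = config or {}
    sf0 = cfg.get("sf", d.DEFAULT_SF)
    speed0 = cfg.get("speed", d.DEFAULT_SPEED)
    disks = cfg.get("disk_diameters", d.DISK_DIAMETERS)
    inners = cfg.get("ring_inner_diameters", d.RING_INNER_DIAMETERS)
    outer = cfg.get("ring_outer_diameter", d.RING_OUTER_DIAMETER)
    key = str(experiment_id)
    conds: list[StimulusCondition] = []

    def add(shape, od, idm, sf, speed):
        for direction in d.DIRECTIONS:
            conds.append(StimulusCondition(shape=shape, outer_diameter=od,
                                           inner_diameter=idm, sf=sf,
                                           speed=speed, direction=direction))

    if key == "1":
        for dd in disks:
            add("disk", dd, 0.0, sf0, speed0)
        for di in inners:
            add("ring", outer, di, sf0, speed0)
    elif key == "2":
        for speed in cfg.get("speeds", d.SPEED_SET):
            for dd in disks:
                add("disk", dd, 0.0, sf0, speed)
    elif key == "3":
        for sf in cfg.get("sfs", d.SF_SET):
            for dd in disks:
                add("disk", dd, 0.0, sf, speed0)
            for di in inners:
                add("ring", outer, di, sf, speed0)
    elif key == "3s":
        for sf in cfg.get("sfs", d.HIGH_SF_SET):
            for dd in cfg.get("disk_diameters", d.SMALL_DIAMETERS):
                add("disk", dd, 0.0, sf, speed0)
    elif key == "4":
        for ecc in inners:
            add("annulus_mask", outer, ecc, sf0, speed0)
    else:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")
    return conds


# ---------------------------------------------------------------------------
# forward model

def amplitude_law(condition: StimulusCondition, truth: BRFTruth) -> float:
    """Signed expected open-loop position change (deg) for one condition.

    Disks follow the DoG summation law of the outer diameter; rings the
    exponential decay of the inner diameter; annulus masks leave the response
    at the full-aperture disk level regardless of mask eccentricity (masking
    a thin ring of the grating does not modulate the response).
    """
    if condition.shape == "disk":
        amp = float(dog_summation_response(condition.outer_diameter,
                                           truth.dog_for(condition.sf)))
    elif condition.shape == "ring":
        amp = float(exp_decay_response(condition.inner_diameter,
                                       truth.decay_for(condition.sf)))
    else:  # annulus_mask
        amp = float(dog_summation_response(condition.outer_diameter,
                                           truth.dog_for(condition.sf)))
    return condition.sign * amp


@dataclass
class EyeTrace:
    """One trial: 1 kHz horizontal/vertical eye position (deg) vs time (ms).

    ``t`` spans fixation (negative times) through the 220+ ms stimulus epoch;
    ``condition`` is None for blank catch trials.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    condition: StimulusCondition | None
    trial_id: int

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("expected a uniform 1 ms grid")

    @property
    def is_blank(self) -> bool:
        return self.condition is None


def _time_grid(pre_ms: int = d.PRE_STIM_MS, post_ms: int = d.POST_STIM_MS) -> np.ndarray:
    return np.arange(-pre_ms, post_ms, dtype=float)


def _unit_position(t: np.ndarray, latency: float) -> np.ndarray:
    """Noiseless unit response: integral of a cubic-smoothstep velocity rise
    (0 before ``latency``, plateau after ``latency + RISE_MS``)."""
    u = np.clip((t - latency) / d.RISE_MS, 0.0, 1.0)
    v = 3 * u**2 - 2 * u**3
    x = np.concatenate(([0.0], np.cumsum((v[1:] + v[:-1]) / 2) * 1e-3))
    return x


def _window_indices(t: np.ndarray, window: tuple[float, float]) -> tuple[int, int]:
    i0 = int(np.searchsorted(t, window[0]))
    i1 = int(np.searchsorted(t, window[1]))
    if i0 >= len(t) or i1 >= len(t):
        raise ValueError(f"window {window} outside recorded epoch")
    return i0, i1


def simulate_trial(condition: StimulusCondition | None, truth: BRFTruth,
                   rng: np.random.Generator, trial_id: int = 0,
                   *, reference_window: tuple[float, float] = d.REFERENCE_WINDOW,
                   pre_ms: int = d.PRE_STIM_MS,
                   post_ms: int = d.POST_STIM_MS) -> EyeTrace:
    """Simulate one trial; blank (drift-only) when ``condition`` is None.

    The noiseless position change over ``reference_window`` equals
    :func:`amplitude_law` exactly, by construction.
    """
    t = _time_grid(pre_ms, post_ms)
    if condition is None:
        slope = rng.normal(0.0, truth.drift_sd)      # deg/s
        x = slope * t * 1e-3
    else:
        unit = _unit_position(t, truth.latency)
        i0, i1 = _window_indices(t, reference_window)
        denom = unit[i1] - unit[i0]
        x = amplitude_law(condition, truth) / denom * unit
    x = x + rng.normal(0.0, truth.noise_sd, size=t.size)
    y = rng.normal(0.0, truth.noise_sd, size=t.size)
    return EyeTrace(t=t, x=x, y=y, condition=condition, trial_id=trial_id)


@dataclass
class Session:
    """An interleaved set of simulated trials plus its generating manifest."""

    traces: list[EyeTrace]
    manifest: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def blanks(self) -> list[EyeTrace]:
        return [tr for tr in self.traces if tr.is_blank]

    @property
    def stimulus_trials(self) -> list[EyeTrace]:
        return [tr for tr in self.traces if not tr.is_blank]


def simulate_session(grid: Sequence[StimulusCondition], truth: BRFTruth,
                     n_trials_per_condition: int, catch_fraction: float = 0.1,
                     seed: int = 0, **trial_kwargs) -> Session:
    """Simulate a full session: exact per-condition trial counts, blank catch
    trials mixed in, all trials interleaved in a seed-reproducible random
    order. Per-trial noise streams derive deterministically from
    ``(seed, trial_index)``.
    """
    if not grid:
        raise ValueError("empty condition grid")
    if n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    n_catch = int(round(len(grid) * n_trials_per_condition * catch_fraction))
    slots: list[StimulusCondition | None] = [c for c in grid
                                             for _ in range(n_trials_per_condition)]
    slots += [None] * n_catch
    order_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0FD]))
    order = order_rng.permutation(len(slots))
    traces = []
    for trial_id, slot in enumerate(np.array(slots, dtype=object)[order]):
        rng = np.random.default_rng(np.random.SeedSequence([seed, trial_id]))
        traces.append(simulate_trial(slot, truth, rng, trial_id, **trial_kwargs))
    manifest = {"n_conditions": len(grid),
                "n_trials_per_condition": n_trials_per_condition,
                "n_catch": n_catch, "seed": seed}
    return Session(traces=traces, manifest=manifest)


def simulate_window_amplitudes(grid: Sequence[StimulusCondition], truth: BRFTruth,
                               n_trials_per_condition: int, seed: int,
                               window: tuple[float, float] = d.REFERENCE_WINDOW,
                               n_catch: int | None = None) -> pd.DataFrame:
    """Blank-corrected per-trial window position changes, without building
    1 kHz traces.

    Samples from exactly the distribution the trace path induces: a trial's
    window change is the (signed) amplitude-law value scaled by the template
    window fraction, plus the difference of two i.i.d. Gaussian position
    noise samples; the blank correction subtracts the mean window change of
    ``n_catch`` simulated catch trials (drift slope times window length plus
    noise). Used for Monte-Carlo recovery studies where full traces would be
    needlessly expensive; agreement with the trace path is covered by tests.

    Returns a DataFrame with one row per (condition, trial) and column ``dx``.
    """
    if not grid:
        raise ValueError("empty condition grid")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA119]))
    t = _time_grid()
    unit = _unit_position(t, truth.latency)
    i0, i1 = _window_indices(t, window)
    r0, r1 = _window_indices(t, d.REFERENCE_WINDOW)
    frac = (unit[i1] - unit[i0]) / (unit[r1] - unit[r0])
    dt_s = (t[i1] - t[i0]) * 1e-3
    if n_catch is None:
        n_catch = int(round(len(grid) * n_trials_per_condition * 0.1))
    n_catch = max(n_catch, 1)
    slopes = rng.normal(0.0, truth.drift_sd, size=n_catch)
    blank_noise = rng.normal(0.0, truth.noise_sd, size=(n_catch, 2))
    blank_mean_dx = float(np.mean(slopes * dt_s + blank_noise[:, 1] - blank_noise[:, 0]))
    rows = []
    for cond in grid:
        a = amplitude_law(cond, truth) * frac
        noise = rng.normal(0.0, truth.noise_sd, size=(n_trials_per_condition, 2))
        dx = a + noise[:, 1] - noise[:, 0] - blank_mean_dx
        for j in range(n_trials_per_condition):
            rows.append({"shape": cond.shape, "outer_diameter": cond.outer_diameter,
                         "inner_diameter": cond.inner_diameter, "sf": cond.sf,
                         "speed": cond.speed, "direction": cond.direction,
                         "trial": j, "dx": dx[j]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O: long-format CSV for traces, JSON manifest

_COND_COLS = ["shape", "outer_diameter", "inner_diameter", "sf", "speed", "direction"]


def session_to_frame(session: Session) -> pd.DataFrame:
    """Long-format table: trial_id, condition fields, t_ms, x_deg, y_deg."""
    parts = []
    for tr in session:
        n = len(tr.t)
        part = pd.DataFrame({"trial_id": np.full(n, tr.trial_id),
                             "t_ms": tr.t, "x_deg": tr.x, "y_deg": tr.y})
        c = tr.condition
        part["shape"] = "blank" if c is None else c.shape
        part["outer_diameter"] = 0.0 if c is None else c.outer_diameter
        part["inner_diameter"] = 0.0 if c is None else c.inner_diameter
        part["sf"] = 0.0 if c is None else c.sf
        part["speed"] = 0.0 if c is None else c.speed
        part["direction"] = "" if c is None else c.direction
        parts.append(part)
    return pd.concat(parts, ignore_index=True)[
        ["trial_id"] + _COND_COLS + ["t_ms", "x_deg", "y_deg"]]


def frame_to_session(frame: pd.DataFrame, manifest: dict | None = None) -> Session:
    traces = []
    for trial_id, grp in frame.groupby("trial_id", sort=True):
        row = grp.iloc[0]
        if row["shape"] == "blank":
            cond = None
        else:
            cond = StimulusCondition(shape=row["shape"],
                                     outer_diameter=float(row["outer_diameter"]),
                                     inner_diameter=float(row["inner_diameter"]),
                                     sf=float(row["sf"]), speed=float(row["speed"]),
                                     direction=row["direction"])
        traces.append(EyeTrace(t=grp["t_ms"].to_numpy(float),
                               x=grp["x_deg"].to_numpy(float),
                               y=grp["y_deg"].to_numpy(float),
                               condition=cond, trial_id=int(trial_id)))
    return Session(traces=traces, manifest=manifest or {})


def write_session(session: Session, out_dir: str | Path) -> tuple[Path, Path]:
    """Write traces.csv and manifest.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_path = out / "traces.csv"
    session_to_frame(session).to_csv(traces_path, index=False, float_format="%.10g")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(session.manifest, indent=2, sort_keys=True))
    return traces_path, manifest_path


def read_session(in_dir: str | Path) -> Session:
    in_dir = Path(in_dir)
    frame = pd.read_csv(in_dir / "traces.csv")
    manifest_path = in_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    return frame_to_session(frame, manifest)
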