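"""Reproducible simulate -> process -> indices -> fit -> tuning pipeline.

Every stage is a pure function of (config, seed); outputs are plain CSV/JSON
files whose content hashes are recorded in a run manifest, so two runs with
the same config are bit-identical end to end.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import defaults as d
from .metrics import index_time_course, model_free_indices
from .models import fit_dog, fit_exp_decay
from .synthetic import (default_truth, make_condition_grid, read_session,
                        simulate_session, write_session)
from .traces import (build_summation_curve, curves_to_frame, frame_to_curves,
                     mean_blank_profile, reject_trials)

__all__ = ["RunConfig", "run_pipeline",
           "stage_simulate", "stage_process", "stage_indices",
           "stage_fit", "stage_tuning"]


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    experiment: Literal["1", "2", "3", "3s", "4"] = "1"
    seed: int
    n_trials: int = Field(20, ge=1)
    catch_fraction: float = Field(0.1, ge=0.0, le=1.0)
    windows: list[tuple[float, float]] = [(65, 85), (85, 105)]
    gsa_criterion: float = d.GSA_CRITERION
    sext_criterion: float = d.SEXT_CRITERION
    amd_criterion: float = d.AMD_CRITERION
    amd_mode: Literal["floor", "peak"] = "floor"
    mu_free: bool = False
    weighted: bool = True
    include_suspect: bool = False
    noise_sd: float = Field(d.NOISE_SD, ge=0)
    drift_sd: float = Field(d.DRIFT_SD, ge=0)
    latency: float = Field(d.LATENCY_MS, gt=0)
    fixation_limit: float = Field(d.FIXATION_LIMIT, gt=0)
    saccade_velocity_limit: float = Field(d.SACCADE_VELOCITY_LIMIT, gt=0)

    @field_validator("experiment", mode="before")
    @classmethod
    def _coerce_experiment(cls, v):
        return str(v)

    @field_validator("windows")
    @classmethod
    def _check_windows(cls, windows):
        if not windows:
            raise ValueError("need at least one analysis window")
        for t0, t1 in windows:
            if not (40 <= t0 < t1 <= 120):
                raise ValueError(f"window ({t0}, {t1}) outside the 40-120 ms "
                                 "open-loop range")
        return [tuple(w) for w in windows]

    @field_validator("gsa_criterion", "sext_criterion", "amd_criterion")
    @classmethod
    def _check_criteria(cls, v):
        if not 0 < v < 1:
            raise ValueError("criterion levels must lie in (0, 1)")
        return v


def _truth(config: RunConfig):
    return default_truth(include_suspect=config.include_suspect,
                         noise_sd=config.noise_sd, drift_sd=config.drift_sd,
                         latency=config.latency)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, float) and math.isnan(o):
        return None
    raise TypeError(f"not JSON serializable: {type(o)}")


def _clean(obj):
    """Replace NaN by None recursively so JSON stays standard."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, out_dir: Path) -> dict:
    grid_cfg = None
    if not config.include_suspect:
        base = {"3": d.SF_SET, "3s": d.HIGH_SF_SET}.get(config.experiment)
        if base is not None:
            grid_cfg = {"sfs": tuple(sf for sf in base if sf not in d.SUSPECT_SFS)}
    grid = make_condition_grid(config.experiment, grid_cfg)
    session = simulate_session(grid, _truth(config), config.n_trials,
                               config.catch_fraction, config.seed)
    write_session(session, out_dir)
    return {"n_conditions": len(grid), "n_trials": len(session.traces),
            "n_catch": len(session.blanks),
            "reduced_n": config.n_trials < 150}


def stage_process(config: RunConfig, out_dir: Path) -> dict:
    session = read_session(out_dir)
    kept, log = reject_trials(session.traces, config.fixation_limit,
                              config.saccade_velocity_limit)
    if not kept:
        raise RuntimeError("all trials rejected")
    blanks = [tr for tr in kept if tr.is_blank]
    blank = mean_blank_profile(blanks)[:2] if blanks else None
    shapes = {tr.condition.shape for tr in kept if tr.condition is not None}
    curves = []
    for window in config.windows:
        for shape in sorted(shapes):
            curves.extend(build_summation_curve(kept, shape, window, blank))
    curves_to_frame(curves).to_csv(out_dir / "curves.csv", index=False,
                                   float_format="%.12g")
    return {"n_kept": len(kept), "n_rejected": len(log),
            "rejections": log[:50], "n_curves": len(curves)}


def stage_indices(config: RunConfig, out_dir: Path) -> dict:
    curves = frame_to_curves(pd.read_csv(out_dir / "curves.csv"))
    by_cell: dict[tuple, dict[str, object]] = {}
    for c in curves:
        cell = by_cell.setdefault((c.window, c.direction, c.sf, c.speed), {})
        cell[c.shape] = c
    records = []
    by_window: dict[tuple[float, float], list] = {}
    for (window, direction, sf, speed), cell in sorted(by_cell.items()):
        disk = cell.get("disk")
        if disk is None:
            continue
        idx = model_free_indices(disk, cell.get("ring"), config.amd_mode)
        by_window.setdefault(window, []).append(idx)
        records.append({"window_t0": window[0], "window_t1": window[1],
                        "direction": direction, "sf": sf, "speed": speed,
                        "gsa": idx.gsa, "sext": idx.sext, "ssi": idx.ssi,
                        "amd": idx.amd, "r_opt": idx.r_opt, "r_asy": idx.r_asy,
                        "flags": list(idx.flags)})
    trends = index_time_course(by_window) if len(by_window) >= 2 else {}
    _write_json(out_dir / "indices.json",
                _clean({"indices": records, "trends": trends}))
    frame = pd.DataFrame([{k: v for k, v in r.items() if k != "flags"}
                          for r in records])
    frame.to_csv(out_dir / "indices.csv", index=False, float_format="%.12g")
    return {"n_cells": len(records), "n_windows": len(by_window)}


def stage_fit(config: RunConfig, out_dir: Path) -> dict:
    curves = frame_to_curves(pd.read_csv(out_dir / "curves.csv"))
    results = []
    n_fail = 0
    for c in curves:
        entry = {"shape": c.shape, "direction": c.direction, "sf": c.sf,
                 "speed": c.speed, "window_t0": c.window[0],
                 "window_t1": c.window[1]}
        try:
            if c.shape == "disk":
                fit = fit_dog(c.diameters, c.amp, c.se,
                              mu_free=config.mu_free, weighted=config.weighted)
                p = fit.params
                entry.update({"model": "dog", "sigma_e": p.sigma_e,
                              "sigma_i": p.sigma_i, "g_e": p.g_e, "g_i": p.g_i,
                              "mu": p.mu})
            elif c.shape == "ring":
                fit = fit_exp_decay(c.diameters, c.amp, c.se,
                                    weighted=config.weighted)
                p = fit.params
                entry.update({"model": "exp_decay", "g_r": p.g_r,
                              "tau": p.tau, "r_0": p.r_0})
            else:
                continue
            entry.update({"chi2_n": fit.chi2_n, "success": fit.success,
                          "stderr": fit.stderr, "flags": fit.flags,
                          "start": list(fit.start)})
        except (RuntimeError, ValueError) as exc:
            n_fail += 1
            entry.update({"model": "failed", "error": str(exc)})
        results.append(entry)
    _write_json(out_dir / "fits.json", _clean({"fits": results}))
    return {"n_fits": len(results), "n_failed": n_fail}


def stage_tuning(config: RunConfig, out_dir: Path) -> dict:
    from .tuning import summarize_across_sf

    fits = json.loads((out_dir / "fits.json").read_text())["fits"]
    idx = pd.read_csv(out_dir / "indices.csv")
    last_window = max(config.windows, key=lambda w: w[0])
    rows: dict[tuple, dict] = {}
    for f in fits:
        if (f["window_t0"], f["window_t1"]) != last_window or "error" in f:
            continue
        row = rows.setdefault((f["direction"], f["sf"]),
                              {"direction": f["direction"], "sf": f["sf"]})
        if f["model"] == "dog":
            row.update({k: f[k] for k in ("sigma_e", "sigma_i", "g_e", "g_i")})
        elif f["model"] == "exp_decay":
            row["tau"] = f["tau"]
    sub = idx[(idx["window_t0"] == last_window[0])
              & (idx["window_t1"] == last_window[1])]
    for _, r in sub.iterrows():
        row = rows.get((r["direction"], r["sf"]))
        if row is not None:
            row.update({k: float(r[k]) for k in ("gsa", "sext", "ssi", "amd")})
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["direction"], r["sf"])))
    if df.empty or df["sf"].nunique() < 3:
        return {"skipped": "needs >= 3 spatial frequencies"}
    summary = summarize_across_sf(df)
    _write_json(out_dir / "tuning.json",
                _clean({"per_sf": summary.per_sf.to_dict(orient="records"),
                        "size_relation": summary.size_relation,
                        "gain_tuning": summary.gain_tuning,
                        "decay_fits": summary.decay_fits}))
    summary.per_sf.to_csv(out_dir / "tuning.csv", index=False,
                          float_format="%.12g")
    return {"n_sfs": int(df["sf"].nunique()),
            "n_replicates": int(df["direction"].nunique())}


_STAGES = [("simulate", stage_simulate), ("process", stage_process),
           ("indices", stage_indices), ("fit", stage_fit),
           ("tuning", stage_tuning)]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages in order and write ``run_manifest.json``.

    The manifest records the config, per-stage status/log, and a SHA-256
    hash of every output file; a stage failure is recorded and re-raised
    after the manifest is written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.model_dump_json()),
                      "stages": {}, "files": {}}
    failure: Exception | None = None
    for name, stage in _STAGES:
        try:
            info = stage(config, out)
            manifest["stages"][name] = {"status": "ok", **info}
        except Exception as exc:  # record partial progress, then stop
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            failure = exc
            break
    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            manifest["files"][path.name] = _sha256(path)
    _write_json(out / "run_manifest.json", _clean(manifest))
    if failure is not None:
        raise RuntimeError(f"pipeline stage failed: {failure}") from failure
    return manifest
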