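"""Whole-pipeline validation studies on synthetic cohorts.

Two studies quantify what the measurement chain delivers under the study
conditions (Table-performance sensor at 1 m, ten repeated captures, stance
variation):

* :func:`run_recovery_cohort` — random phantoms are measured end to end and
  the recovered parameters regressed on their ground truth;
* :func:`repeat_dispersion` — one animal is measured many times and the
  empirical scatter per parameter is compared with the uncertainty budget.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import body_params as bp
from .compare_stats import linear_regression
from .landmarks import DetectionError
from .pipeline import PipelineConfig, run_pipeline, simulate_views, extract_parameters
from .phantom import generate_cow_phantom
from .render import Posture
from .sensor import SensorModel
from .calibration import calibrate_sensor
from .uncertainty import load_budget

__all__ = ["run_recovery_cohort", "repeat_dispersion"]

RECOVERY_PARAMETERS = bp.PARAMETER_FIELDS


def run_recovery_cohort(n_phantoms: int = 20, repeats: int = 10,
                        preset: str = "calf", working_distance: float = 1000.0,
                        seed: int = 0) -> dict:
    """Measure ``n_phantoms`` random phantoms end to end.

    Returns ``{"table": DataFrame, "regressions": {param: RegressionResult},
    "n_failed": int}``; the table holds truth and recovered value per animal
    and parameter.
    """
    rows = []
    n_failed = 0
    for i in range(n_phantoms):
        cfg = PipelineConfig(
            preset=preset, seed=(seed * 1009 + i) % (2 ** 31),
            repeats=repeats, working_distance=working_distance,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_pipeline(cfg)
        except DetectionError:
            n_failed += 1
            continue
        truth = res.phantom.truth
        for name in RECOVERY_PARAMETERS:
            rows.append({
                "animal": i, "parameter": name,
                "truth": getattr(truth, name),
                "measured": getattr(res.aggregate, name),
                "sd": res.aggregate.dispersion.get(name, np.nan),
            })
    table = pd.DataFrame(rows)
    regressions = {}
    for name, grp in table.groupby("parameter"):
        ok = grp.dropna(subset=["measured"])
        if len(ok) >= 3:
            regressions[name] = linear_regression(ok["truth"], ok["measured"])
    return {"table": table, "regressions": regressions, "n_failed": n_failed}


def repeat_dispersion(n_extractions: int = 50, preset: str = "calf",
                      working_distance: float = 1000.0, seed: int = 0) -> dict:
    """Empirical scatter of repeated single-capture extractions of one animal.

    The same phantom is captured ``n_extractions`` times (sensor noise and
    stance jitter vary per capture); the per-parameter standard deviation is
    compared with the matching uncertainty budget's combined standard
    uncertainty U/k resolved at the parameter's own magnitude.
    """
    rng = np.random.default_rng(seed)
    phantom = generate_cow_phantom(preset, seed=int(rng.integers(2 ** 31)))
    sensor = SensorModel.at_distance(working_distance)
    correction = calibrate_sensor(sensor, seed=int(rng.integers(2 ** 31)))
    cfg = PipelineConfig(preset=preset, seed=seed,
                         working_distance=working_distance, repeats=1)
    session = Posture(
        pitch_deg=float(rng.normal(0.0, cfg.posture_pitch_sd)),
        height_offset=float(rng.normal(0.0, cfg.posture_height_sd)),
    )
    results = []
    for _ in range(n_extractions):
        posture = Posture(
            pitch_deg=session.pitch_deg + float(rng.normal(0, cfg.capture_pitch_sd)),
            height_offset=session.height_offset + float(rng.normal(0, cfg.capture_height_sd)),
        )
        frames = simulate_views(phantom, sensor, cfg.views, rng, posture)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                results.append(extract_parameters(frames, cfg, correction))
            except DetectionError:
                continue
    budget = load_budget("kinect-1", "upper")
    out = {}
    for name in RECOVERY_PARAMETERS:
        vals = np.array([getattr(r, name) for r in results], float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 10 or name == "back_slope":
            continue  # budget entries are lengths (mm)
        b = load_budget("kinect-1", "upper",
                        measurand_length=max(float(np.mean(vals)), 100.0))
        out[name] = {
            "sd": float(vals.std(ddof=1)),
            "allowed": b.combined,  # U / k
            "n": int(len(vals)),
        }
    return {"phantom": phantom, "dispersion": out,
            "n_extractions": len(results), "budget_k": budget.k}
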