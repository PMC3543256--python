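"""Synthetic accuracy studies: the end-to-end protocol on simulated sessions.

These helpers run the full pipeline — simulate a calibration session,
collect the training set, fit the neural mapping (and the linear
baseline), run the pseudo-random test session and score both phases in
degrees of visual angle — for one or many seeds.  They back the
acceptance checks and give users a one-call reproduction of the
synthetic benchmark.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import SessionResult, rmse_components
from .geometry import ScreenGeometry
from .mapping import GazeModel, TrainConfig, fit_gaze_model, fit_linear_baseline, predict_pog
from .protocol import ScheduleConfig, make_calibration_grid, make_test_grid, run_calibration, run_test
from .synth import SimParams, setting_preset, simulate_session

__all__ = ["run_synthetic_session", "run_synthetic_study"]


def _score(model: GazeModel, samples, phase: str, screen: ScreenGeometry) -> float:
    truth = np.array([s.true_pog for s in samples])
    est = np.array([predict_pog(model, s.features) for s in samples])
    res = SessionResult.from_pairs(truth, est, phase=phase)
    return rmse_components(res, screen).deg_RMSE_rho


def run_synthetic_session(
    seed: int,
    sim: Optional[SimParams] = None,
    screen: Optional[ScreenGeometry] = None,
    train_cfg: Optional[TrainConfig] = None,
    baseline: bool = True,
) -> dict:
    """One full simulated calibration + test run; RMSE in degrees.

    Returns a dict with the calibration- and test-grid radial RMSE of
    the neural model and, when the feature data has full rank, of the
    linear baseline (``None`` otherwise, e.g. for noise-free sessions
    whose features lie exactly on the 2-D gaze manifold).
    """
    screen = screen or ScreenGeometry()
    sim = sim or setting_preset(1)
    sched = ScheduleConfig(seed=seed)
    cal_grid = make_calibration_grid(screen)
    test_grid = make_test_grid(cal_grid)
    cal_samples = simulate_session(cal_grid, sched, sim, seed=seed)
    test_samples = simulate_session(test_grid, sched, sim, seed=seed + 1)
    train = run_calibration((s.features for s in cal_samples), cal_grid, sched)
    cfg = dataclasses.replace(train_cfg or TrainConfig(), seed=seed)
    model = fit_gaze_model(train, screen, cfg)
    out = {
        "seed": seed,
        "mfnn_cal_deg": _score(model, cal_samples, "calibration", screen),
        "mfnn_test_deg": _score(model, test_samples, "test", screen),
        "linear_test_deg": None,
        "linear_cal_deg": None,
    }
    # exercise the stream-based test runner as well (same predictions)
    res = run_test(model, (s.features for s in test_samples), test_grid, sched)
    out["mfnn_test_deg_stream"] = rmse_components(res, screen).deg_RMSE_rho
    if baseline:
        try:
            lin = fit_linear_baseline(train, screen)
        except ValueError:
            lin = None
        if lin is not None:
            out["linear_cal_deg"] = _score(lin, cal_samples, "calibration", screen)
            out["linear_test_deg"] = _score(lin, test_samples, "test", screen)
    return out


def run_synthetic_study(
    seeds: Sequence[int],
    sim: Optional[SimParams] = None,
    screen: Optional[ScreenGeometry] = None,
    train_cfg: Optional[TrainConfig] = None,
    baseline: bool = True,
) -> pd.DataFrame:
    """The per-seed benchmark table over a list of seeds."""
    rows = [run_synthetic_session(int(s), sim=sim, screen=screen,
                                  train_cfg=train_cfg, baseline=baseline)
            for s in seeds]
    return pd.DataFrame(rows)
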