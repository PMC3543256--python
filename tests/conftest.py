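import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from neurogaze import (
    DetectorConfig,
    ScreenGeometry,
    ScheduleConfig,
    make_calibration_grid,
    make_test_grid,
)
from neurogaze import synth


@pytest.fixture(scope="session")
def screen() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def cal_grid(screen):
    return make_calibration_grid(screen)


@pytest.fixture(scope="session")
def test_grid(cal_grid):
    return make_test_grid(cal_grid)


@pytest.fixture
def detector_cfg() -> DetectorConfig:
    return DetectorConfig()


@pytest.fixture
def sim_noise_free() -> synth.SimParams:
    return dataclasses.replace(synth.SimParams(), feature_noise_sigma_px=0.0)


def make_session(grid, sim, seed, sched_seed=None):
    """Feature-level simulated session for the given grid."""
    sched = ScheduleConfig(seed=seed if sched_seed is None else sched_seed)
    return synth.simulate_session(grid, sched, sim, seed=seed), sched
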