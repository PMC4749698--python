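"""Shared fixtures: one model system and one set of expensive simulation
runs (behavioral grid, traced medium-speed trials, metabolic battery) reused
across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from artgc.config import ExperimentConfig
from artgc.fmri import battery_floors, run_battery
from artgc.system import build_system
from artgc.task import (
    CONDITIONS,
    SPEEDS,
    TrialSpec,
    calibrate,
    run_grid,
    run_trial,
)


@pytest.fixture(scope="session")
def system():
    return build_system(ExperimentConfig())


@pytest.fixture(scope="session")
def grid_outcomes(system):
    """Same-response grid (3 conditions x 3 speeds), untraced."""
    return run_grid(system, record=False)


@pytest.fixture(scope="session")
def calibrated_outcomes(system, grid_outcomes):
    cfg = system.config
    cal = calibrate(
        grid_outcomes,
        cfg.calibration.anchor_interference_ms,
        cfg.calibration.neutral_rt_ms,
    )
    return {k: o.with_calibration(cal) for k, o in grid_outcomes.items()}, cal


@pytest.fixture(scope="session")
def traced_trials():
    """Medium-speed trials run to a high motor threshold with full traces,
    for threshold-robustness and time-course assertions."""
    cfg = ExperimentConfig()
    cfg.response.motor_threshold = 1.0
    sys_ = build_system(cfg)
    out = {}
    for cond in CONDITIONS:
        sys_.color.set_r_preset("medium")
        out[cond] = run_trial(
            TrialSpec(condition=cond, r_speed="medium"), sys_, record=True
        )
    return out


@pytest.fixture(scope="session")
def battery(system):
    summaries = run_battery(system)
    floors = battery_floors(summaries, system.config.fmri.floor_fraction)
    return summaries, floors
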