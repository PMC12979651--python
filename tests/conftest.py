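"""Shared fixtures: geometry, small stream builders, and session-scoped
end-to-end pipeline runs on the default (group-contrasted) and null
(identical-parameters) synthetic cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gazecue.io_cli import PipelineConfig, run_pipeline
from gazecue.preprocess import ScreenGeometry
from gazecue.synthetic_data import TD_PARAMS, CohortSpec, TaskConfig


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


def make_stream(x, y, fs=300.0, valid=None, t0=0.0) -> pd.DataFrame:
    """Build a gaze stream frame from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return pd.DataFrame({
        "time_s": t0 + np.arange(n) / fs,
        "x_norm": x, "y_norm": y, "valid": np.asarray(valid, dtype=bool),
    })


def step_stream(geometry, n_fix=150, n_sacc=30, amp_norm=0.25, fs=300.0) -> pd.DataFrame:
    """Fixation - smooth step displacement - fixation, saccade well above threshold."""
    x0, x1 = 0.4, 0.4 + amp_norm
    ramp = x0 + amp_norm / (1.0 + np.exp(-np.linspace(-6, 6, n_sacc)))
    x = np.concatenate([np.full(n_fix, x0), ramp, np.full(n_fix, x1)])
    y = np.full(x.size, 0.5)
    return make_stream(x, y, fs=fs)


@pytest.fixture(scope="session")
def effect_pipeline():
    """Full pipeline on the default cohort (19 ADHD / 27 TD, seeded)."""
    return run_pipeline(PipelineConfig().with_seed(1))


@pytest.fixture(scope="session")
def null_pipeline():
    """Full pipeline on a null cohort: identical parameters for both groups.

    Questionnaire locations sit mid-range so the eligibility filters treat
    the two (identically distributed) groups symmetrically.
    """
    neutral = dict(kars_inattention=(7.5, 1.0), kars_hyperactivity=(4.0, 1.0))
    gp = dataclasses.replace(TD_PARAMS, **neutral)
    cfg = dataclasses.replace(
        PipelineConfig().with_seed(1),
        cohort=CohortSpec(n_adhd=19, n_td=27, adhd=gp, td=gp, seed=1))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    """Small, fast cohort for IO/CLI and determinism tests."""
    return dataclasses.replace(
        PipelineConfig(),
        cohort=CohortSpec(n_adhd=2, n_td=2, seed=5),
        task=TaskConfig(n_blocks=2, trials_per_block=12),
        cv_repeats=5, seed=5)
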