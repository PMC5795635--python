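"""Shared fixtures: small synthetic cohorts and trained models.

Heavy fixtures are session-scoped so the forests are trained once; the
reduced protocol keeps the streams short while preserving every class.
"""

from __future__ import annotations

import numpy as np
import pytest

from wristhar import evaluate, simulate
from wristhar.recognition import FRule, RFConfig
from wristhar.windows import DAILY_CONFIG, EXERCISE_CONFIG

REDUCED_PROTOCOL = (
    ("walking", {"duration": 14.0}),
    ("running", {"duration": 14.0}),
    ("sitting_down", {"reps": 5}),
    ("standing_up", {"reps": 5}),
    ("seated", {"duration": 14.0}),
    (simulate.SWITCH_CLASS, {"reps": 5}),
    ("front_step_down", {"reps": 4}),
    ("squat_chair", {"reps": 4}),
    ("front_lunge", {"reps": 4}),
    ("sit_to_stand", {"reps": 4}),
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate.default_cohort(n_subjects=3, seed=11, jitter=0.05,
                                   protocol=REDUCED_PROTOCOL)


@pytest.fixture(scope="session")
def daily_dataset(small_cohort):
    return evaluate.build_dataset(small_cohort, DAILY_CONFIG,
                                  classes=evaluate.DAILY_MODEL_CLASSES)


@pytest.fixture(scope="session")
def exercise_dataset(small_cohort):
    return evaluate.build_dataset(small_cohort, EXERCISE_CONFIG,
                                  classes=evaluate.EXERCISE_MODEL_CLASSES)


@pytest.fixture(scope="session")
def dual_models(small_cohort):
    """(daily_model, exercise_model, energy_profile) on the small cohort."""
    return evaluate.train_dual_models(
        small_cohort,
        daily_cfg=RFConfig(B=25, F_rule=FRule.HALF_SQRT_M, seed=0),
        exercise_cfg=RFConfig(B=25, F_rule=FRule.SQRT_M, seed=0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
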