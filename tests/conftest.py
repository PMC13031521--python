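import numpy as np
import pytest

from gaitscore.modeling import ModelConfig
from gaitscore.simulate import CohortSpec, default_profile, simulate_cohort, simulate_walk


@pytest.fixture(scope="session")
def walk():
    """One deterministic mid-severity walk (5 s at 30 fps)."""
    return simulate_walk(default_profile("2"), fps=30, duration=5.0, seed=7)


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free grade-1 profile for closed-form trajectory checks."""
    return default_profile("1", jitter_px=0.0, dropout_rate=0.0,
                           step_interval_cv=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Small multi-grade cohort (2 subjects per class, single visits)."""
    spec = CohortSpec(
        n_subjects={g: 2 for g in ("HC", "0", "1", "2", "3", "4")},
        seed=11,
        duration=6.0,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-search gbt config so model tests stay quick."""
    return ModelConfig(
        feature_set="catalogue",
        predictor="gbt",
        n_tuning_trials=2,
        inner_folds=3,
        gbt_estimator_range=(50, 120),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
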