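import numpy as np
import pytest

from crowdkit.bold_pipeline import HRFParams
from crowdkit.synthetic_data import (
    BoldConfig,
    ObserverParams,
    PopulationParams,
    StudyConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def default_study():
    return StudyConfig(seed=42)


@pytest.fixture
def small_study():
    return StudyConfig(
        n_subjects=3, n_days=2, trials_per_condition_per_day=60, seed=123
    )


@pytest.fixture
def observer():
    return ObserverParams(
        subject_id="S01",
        c_rad_pre=2.16,
        c_tan_pre=1.61,
        c_rad_post=1.46,
        c_tan_post=1.05,
        learn_tau=1.0,
        sigma_psy=0.45,
        lapse=0.02,
    )


@pytest.fixture
def quiet_bold():
    """Deterministic BOLD config: no noise, no drift, no amplitude jitter."""
    return BoldConfig(noise_sd=0.0, drift_slope=0.0, amplitude_jitter_sd=0.0)


@pytest.fixture
def default_bold():
    return BoldConfig()
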