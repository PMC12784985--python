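import numpy as np
import pytest

from broilerweight.growth_model import RichardsParams
from broilerweight.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-design cohort (100 birds x 42 days) with default noise."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy cohort for fast protocol tests."""
    return generate_cohort(CohortConfig(n_birds=16, seed=7))


@pytest.fixture(scope="session")
def noise_free_config():
    return CohortConfig(
        n_birds=10,
        seed=3,
        noise_cv_weight=0.0,
        morphometric_noise_cv=0.0,
        pixel_noise_cv=0.0,
        bird_effect_cv=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return generate_cohort(noise_free_config)


@pytest.fixture
def male_params():
    return RichardsParams(A=6000.87, B=200.0, k=0.1327, m=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
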