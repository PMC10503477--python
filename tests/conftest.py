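import numpy as np
import pytest

from pigait.cohort import generate_cohort
from pigait.config import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy longitudinal cohort shared across read-only tests."""
    cfg = CohortConfig(n_aga=6, n_sga=4, ages=(1.0, 8.0, 28.0), strides_per_recording=2)
    return generate_cohort(cfg, seed=101)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free cohort: dynamic-similarity invariants hold exactly."""
    cfg = CohortConfig(
        n_aga=5, n_sga=3, ages=(1.0, 8.0, 28.0), strides_per_recording=2
    ).with_zero_noise()
    # keep body-size spread (structural variation, not measurement noise)
    # so same-age piglets of different size exist
    cfg.aga_mass_sd = 0.3
    return generate_cohort(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
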