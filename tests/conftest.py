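import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyssync import synthetic_cohort as sc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort() -> sc.Cohort:
    """One full default cohort (23 dyssynchrony / 7 without), all artifacts."""
    return sc.generate_cohort(sc.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort() -> sc.Cohort:
    """Small noise-free cohort for round-trip checks."""
    cfg = sc.CohortConfig(
        seed=11,
        n_dys=3,
        n_nondys=2,
        noise=sc.NoiseParams(tac_noise_scale=0.0, suv_segment_jitter_sd=0.0),
    )
    return sc.generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
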