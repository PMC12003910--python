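import logging

import pytest
from hypothesis import HealthCheck, settings

import luckydoor as ld
from luckydoor.montage import default_montage

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("luckydoor").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort with the default injected behavior effect."""
    cov = ld.generate_covariates((10, 8, 10), rng=101)
    beh = ld.generate_cohort_behavior(cov, rng=202)
    return cov, beh


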