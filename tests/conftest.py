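import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ccmosaic import simdata  # noqa: E402


@pytest.fixture(scope="session")
def small_panel():
    """One 100 kb chromosome, 60 markers."""
    return simdata.simulate_founder_panel(1, 100_000, 60, allele_seed=11)


@pytest.fixture(scope="session")
def dense_panel():
    """One 1 Mb chromosome, 2000 markers (HMM recovery scale)."""
    return simdata.simulate_founder_panel(1, 1_000_000, 2000, allele_seed=6)
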