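import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    from spermqpcr import load_table1

    return load_table1()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (seed 11)."""
    from spermqpcr import SyntheticCohortConfig, simulate_cohort

    cfg = SyntheticCohortConfig(seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
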