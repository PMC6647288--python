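import pytest
from hypothesis import HealthCheck, settings

from nucleolink import synthetic_data as sd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim():
    """One full default-scale simulation shared across the suite."""
    return sd.simulate_all(sd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def annotation(sim):
    return sim["annotation"]


@pytest.fixture(scope="session")
def categories(sim):
    return sim["categories"]


@pytest.fixture(scope="session")
def igrs(sim):
    return sim["igrs"]
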