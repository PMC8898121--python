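import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ferrohem import make_extinction_fixture, reported_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def extinction():
    return make_extinction_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def printed_params():
    """The study's mean fitted kinetic parameter set at 1700 µM Fe2+."""
    return reported_params()
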