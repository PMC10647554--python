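import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from walkbout.simulate import build_scenario, corridor_protocol  # noqa: E402


@pytest.fixture(scope="session")
def corridor():
    """One corridor-protocol recording shared across tests (deterministic)."""
    return build_scenario(corridor_protocol(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
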