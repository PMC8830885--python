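import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sirspread import scenarios as sc

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_scenario():
    """A boundary scenario shared across tests (anchor + boundary at 5 kb)."""
    return sc.boundary_scenario(seed=1)


@pytest.fixture(scope="session")
def sim_calls(sim_scenario):
    return sim_scenario.simulate()


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh deterministic stream,
    # so results do not depend on test execution order
    return np.random.default_rng(12345)
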