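import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    from onecarbon import default_parameters

    return default_parameters()


@pytest.fixture(scope="session")
def baseline(params):
    from onecarbon import solve_steady_state

    return solve_steady_state(params, lri=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
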