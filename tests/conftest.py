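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


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def anchored_scenario():
    """One mini demo scenario in the anchored (genes-vs-region) layout."""
    from fivec.simulate import build_scenario, mini_hoxa_params

    return build_scenario(mini_hoxa_params(), seed=1, scheme="anchored")


@pytest.fixture(scope="session")
def alternating_scenario():
    """One mini demo scenario in the alternating (all-vs-all) layout."""
    from fivec.simulate import build_scenario, mini_hoxa_params

    return build_scenario(mini_hoxa_params(), seed=1, scheme="alternating")
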