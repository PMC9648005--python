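import numpy as np
import pytest

from chondro.attractors import default_signatures, monte_carlo
from chondro.engine import EngineConfig
from chondro.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def toggle():
    return make_fixture(FixtureSpec(kind="toggle_switch"))


@pytest.fixture(scope="session")
def source_toggle():
    return make_fixture(FixtureSpec(kind="source_toggle"))


@pytest.fixture(scope="session")
def chain3():
    return make_fixture(FixtureSpec(kind="chain", n_components=3))


@pytest.fixture(scope="session")
def mini():
    return make_fixture(FixtureSpec(kind="mini_chondro"))


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def mini_canalization(mini, signatures):
    """A cached Monte Carlo run on the demo network (3 labeled attractors)."""
    result = monte_carlo(
        mini, n_init=600, config=EngineConfig(seed=11), signatures=signatures
    )
    labels = {a.label for a in result.attractors}
    assert {"Healthy", "Hypertrophic", "None"} <= labels
    return result


@pytest.fixture(scope="session")
def mini_refs(mini_canalization):
    return mini_canalization.attractors


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
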