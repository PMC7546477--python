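import numpy as np
import pytest

from dfbasis.fixtures import make_example1, make_toy_community, make_toy_model


@pytest.fixture
def example1():
    """The worked degenerate dynamic LP: (system, gamma)."""
    return make_example1()


@pytest.fixture
def toy_static():
    """Single-organism toy GEM with static bounds and closed-form notes."""
    return make_toy_model(0, 2, 2, uptake="static")


@pytest.fixture
def toy_community():
    """Two-organism toy community with mass-action uptake bounds."""
    return make_toy_community(7, 2, 2, 2, uptake="linear")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
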