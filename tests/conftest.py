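import numpy as np
import pytest

from lfpreach.cable import PassiveParams, discretize
from lfpreach.morphology import Morphology, Segment
from lfpreach.presets import l4_like, l5_like


@pytest.fixture(scope="session")
def passive():
    return PassiveParams()


@pytest.fixture(scope="session")
def two_comp_morph():
    """Minimal two-cylinder cell used for hand-checkable cable solutions."""
    return Morphology([
        Segment(0, -1, [0.0, 0.0, 0.0], [0.0, 0.0, 100.0], 10.0, "soma"),
        Segment(1, 0, [0.0, 0.0, 100.0], [0.0, 0.0, 200.0], 10.0, "basal"),
    ])


@pytest.fixture(scope="session")
def two_comp_model(two_comp_morph, passive):
    return discretize(two_comp_morph, passive, max_compartment_length=100.0)


@pytest.fixture(scope="session")
def one_comp_model(passive):
    m = Morphology([Segment(0, -1, [0, 0, 0], [0, 0, 20.0], 20.0, "soma")])
    return discretize(m, passive, max_compartment_length=25.0)


@pytest.fixture(scope="session")
def l5_model(passive):
    """Coarsely discretized stylized deep pyramidal cell (fast tests)."""
    return discretize(l5_like(), passive, max_compartment_length=40.0)


@pytest.fixture(scope="session")
def l4_model(passive):
    return discretize(l4_like(), passive, max_compartment_length=40.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
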