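import numpy as np
import pytest

import patchyring as pr
from patchyring.geometry import SimulationBox, make_ring_target, random_configuration
from patchyring.potentials import InteractionParams


@pytest.fixture(scope="session")
def box8():
    return SimulationBox.cubic(8.0)


@pytest.fixture(scope="session")
def ring8(box8):
    return make_ring_target(8, box8)


@pytest.fixture(scope="session")
def ring10():
    return make_ring_target(10, SimulationBox.cubic(9.0))


@pytest.fixture(scope="session")
def ring13():
    return make_ring_target(13, SimulationBox.cubic(15.0))


@pytest.fixture
def params10():
    """Default interactions with a 10 kJ/mol cross-state patch well."""
    return InteractionParams().with_depth(10.0, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
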