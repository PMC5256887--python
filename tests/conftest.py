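import numpy as np
import pytest

from actomyo.params import Domain, ParameterSet
from actomyo.state import Filament, SimulationState


@pytest.fixture
def params():
    return ParameterSet()


@pytest.fixture
def domain():
    return Domain()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def state_with_filaments(point_sets, params=None, domain=None, seed=0):
    """Bare state holding explicitly constructed filaments."""
    params = params or ParameterSet()
    domain = domain or Domain()
    fils = [Filament(np.asarray(pts, dtype=float)) for pts in point_sets]
    return SimulationState(domain=domain, params=params, filaments=fils,
                           acps=[], motors=[], monomer_pool=0, free_acp=0,
                           free_motor=0, rng=np.random.default_rng(seed))


@pytest.fixture
def make_state():
    return state_with_filaments
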