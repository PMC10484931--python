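import numpy as np
import pytest

from foldpool import fixtures
from foldpool.assembly import ModelPool


@pytest.fixture
def helix20():
    return fixtures.make_helix(20)


@pytest.fixture
def helix30():
    return fixtures.make_helix(30)


@pytest.fixture
def small_pool(helix30):
    """Six decoys at three noise levels with known quality ordering."""
    return fixtures.make_pool(helix30, sigmas=[0.3, 0.3, 0.8, 0.8, 2.0, 2.0], seeds=[7])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
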