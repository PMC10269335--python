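import numpy as np
import pytest

from pnadyn import fixtures as fx
from pnadyn.dihedral_fit import DihedralSeries, DihedralTerm


@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


@pytest.fixture
def straight_recipe():
    """Noise-free straight 8-bp pseudo-duplex."""
    return fx.DuplexRecipe(programmed_bend=0.0, noise_sd=0.0, seed=11)


@pytest.fixture
def bent_recipe():
    return fx.DuplexRecipe(programmed_bend=23.0, noise_sd=0.0, seed=11)


@pytest.fixture
def three_term_series():
    return DihedralSeries((
        DihedralTerm(1.2, 1, 0.0),
        DihedralTerm(0.7, 2, 180.0),
        DihedralTerm(2.4, 3, 0.0),
    ))


def random_rigid_transform(rng):
    """A uniform random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31 - 1))))
    t = rng.uniform(-20, 20, 3)
    return R.as_matrix(), t
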