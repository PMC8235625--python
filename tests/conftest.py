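import numpy as np
import pytest

import callimorph as cm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def atlas():
    return cm.make_template(seed=1)


@pytest.fixture(scope="session")
def small_dataset(atlas):
    recipe = cm.SimulationRecipe(seed=7, n_taxa=8, n_specimens_per_species=2)
    return cm.generate_dataset(recipe, atlas=atlas, with_meshes=True)


@pytest.fixture(scope="session")
def fixture_tree():
    return cm.callitrichid_tree()


@pytest.fixture(scope="session")
def fixture_traits():
    return cm.callitrichid_traits()


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rigid_copy(points, rng, scale=True):
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    return s * points @ random_rotation(rng) + rng.normal(0, 5, size=3)
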