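import numpy as np
import pytest

from fractalarbor import arbor as fa
from fractalarbor import synthetic as fs


@pytest.fixture(scope="session")
def cylinder_arbor():
    """Single horizontal cylinder, r = 0.5 µm, l = 10 µm."""
    nodes = [
        fa.CenterlineNode(1, [0.0, 0.0, 0.0], 0.5, None),
        fa.CenterlineNode(2, [10.0, 0.0, 0.0], 0.5, 1),
    ]
    return fa.CenterlineArbor(nodes)


@pytest.fixture(scope="session")
def fork_arbor():
    """Soma, a 5 µm trunk, and two symmetric 100° fork branches."""
    c, s = np.cos(np.deg2rad(80.0)), np.sin(np.deg2rad(80.0))
    nodes = [
        fa.CenterlineNode(1, [0.0, 0.0, 0.0], 0.5, None, fa.SOMA),
        fa.CenterlineNode(2, [5.0, 0.0, 0.0], 0.5, 1),
        fa.CenterlineNode(3, [10.0, 0.0, 0.0], 0.5, 2),
        fa.CenterlineNode(4, [10.0 - 5.0 * c, 5.0 * s, 0.0], 0.5, 3),
        fa.CenterlineNode(5, [10.0 - 5.0 * c, -5.0 * s, 0.0], 0.5, 3),
    ]
    return fa.CenterlineArbor(nodes)


@pytest.fixture(scope="session")
def small_htree():
    """Straight 5-level H-tree, D = 1.4, L1 = 50 µm."""
    return fs.generate_htree(fs.HTreeSpec(D_target=1.4, levels=5, L_1=50.0))


@pytest.fixture(scope="session")
def toy_arbor():
    return fs.generate_toy_arbor(fs.ToyArborSpec(n_levels=5, seed=11))


@pytest.fixture(scope="session")
def icosphere():
    return fs.generate_sphere_mesh(10.0, refinement=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
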