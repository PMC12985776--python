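import numpy as np
import pytest

from inie.phantom import generate_vessel_tree, ground_truth_diagram, rasterize_phantom


@pytest.fixture(scope="session")
def ring_image():
    """Annulus on a flat background: one component, one hole."""
    g = 64
    yy, xx = np.mgrid[0:g, 0:g]
    r = np.hypot(yy - g / 2, xx - g / 2)
    return 0.1 + 0.9 * ((r > 10) & (r < 14)).astype(float)


@pytest.fixture(scope="session")
def two_loop_phantom():
    tree = generate_vessel_tree(7, n_loops=2)
    return rasterize_phantom(tree, 128)


@pytest.fixture(scope="session")
def two_loop_diagram(two_loop_phantom):
    return ground_truth_diagram(two_loop_phantom)


def random_diagram(rng, n):
    b = rng.random(n)
    return np.column_stack((b, b + rng.random(n) * 0.5))
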