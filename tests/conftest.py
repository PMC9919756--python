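import numpy as np
import pytest

from hspoly.chain_model import Configuration, SystemParams


@pytest.fixture
def default_params():
    return SystemParams()


@pytest.fixture
def straight_trimer():
    """One straight 3-mer of tangent spheres in a large box."""
    return Configuration(50.0, [np.array([[5.0, 5, 5], [6, 5, 5], [7, 5, 5]])])


@pytest.fixture
def trimer_params():
    return SystemParams(n_chains=1, n_av=3, length_bounds=(3, 3))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
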