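import numpy as np
import pytest

from bsfourier import BSFModel
from bsfourier.synthetic import make_ground_truth, make_registration_set


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def truth_model():
    """Small smooth cyclic ground-truth motion (24^3 voxel domain)."""
    return make_ground_truth(grid=24, period=10, n_modes=2, amplitude=1.5,
                             smoothness=10.0, seed=3)


@pytest.fixture(scope="session")
def exact_reg(truth_model):
    """Registration set exactly consistent with `truth_model`."""
    return make_registration_set(truth_model, grid=24, noise=0.0)


@pytest.fixture()
def random_model(rng):
    """Anisotropic random-lattice model for brute-force oracle checks."""
    n_modes, P = 2, 9
    lattice = rng.normal(size=(6, 5, 7, 2 * n_modes + 1, 3))
    return BSFModel(lattice, spacing=(2.0, 1.5, 1.0),
                    origin=(-2.0, -1.5, -1.0), period=P, n_modes=n_modes)


@pytest.fixture()
def identity_model():
    """Static model equal to its affine map (isotropic spacing 2 mm)."""
    g, n_modes = 6, 1
    lattice = np.zeros((g, g, g, 2 * n_modes + 1, 3))
    spacing = np.full(3, 2.0)
    origin = np.full(3, -2.0)
    coords = origin[0] + np.arange(g) * spacing[0]
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
    lattice[..., 0, 0] = X
    lattice[..., 0, 1] = Y
    lattice[..., 0, 2] = Z
    return BSFModel(lattice, spacing, origin, period=8, n_modes=n_modes)
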