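import numpy as np
import pytest

from tcplan.grids import VoxelGrid
from tcplan.phantom import PhantomConfig, generate_phantom
from tcplan.radiobiology import RadiobioParams, discretize_alpha
from tcplan.uncertainty import PROSTATE_ERROR_PRESET, ZERO_ERROR


@pytest.fixture(scope="session")
def default_patient():
    """One default synthetic patient, shared (read-only) across tests."""
    return generate_phantom(PhantomConfig(), seed=1)


@pytest.fixture(scope="session")
def params():
    return RadiobioParams()


@pytest.fixture(scope="session")
def alpha_dist():
    return discretize_alpha()


@pytest.fixture(scope="session")
def error_model():
    return PROSTATE_ERROR_PRESET


@pytest.fixture(scope="session")
def zero_error():
    return ZERO_ERROR


@pytest.fixture(scope="session")
def small_grid():
    """A 20^3 grid used by the expectation-oracle tests."""
    return VoxelGrid(shape=(20, 20, 20), spacing=(2.0, 2.0, 2.5))


def make_small_instance(grid, seed=0, n_ctv_radius_mm=12.0):
    """Small random dose/clonogen instance on a given grid (shared helper)."""
    rng = np.random.default_rng(seed)
    xx, yy, zz = grid.coordinates()
    c = grid.center
    ctv = (
        ((xx - c[0]) / n_ctv_radius_mm) ** 2
        + ((yy - c[1]) / n_ctv_radius_mm) ** 2
        + ((zz - c[2]) / n_ctv_radius_mm) ** 2
    ) <= 1.0
    rho = np.zeros(grid.shape)
    rho[ctv] = rng.uniform(100.0, 2000.0, ctv.sum())
    d = 2.0 + 0.4 * rng.standard_normal(grid.shape)
    d = np.clip(d, 0.0, None)
    # smooth the dose a little so interpolation error is small
    from scipy import ndimage

    d = ndimage.gaussian_filter(d, 1.0)
    return ctv, rho, d
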