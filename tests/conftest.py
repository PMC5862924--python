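import numpy as np
import pytest

from propct import (
    ConeBeamGeometry,
    PhantomParams,
    build_cochlea_phantom,
    wavelength,
)

# The compact-source scan geometry (F_eff ~ 0.61) used throughout the suite.
MUCLS = dict(z01_mm=3769.0, z02_mm=4856.5, pixel_um=6.5, energy_kev=25.0)


@pytest.fixture(scope="session")
def mucls_geom() -> ConeBeamGeometry:
    return ConeBeamGeometry(**MUCLS, source_fwhm_um=98.0)


@pytest.fixture(scope="session")
def lam25() -> float:
    return wavelength(25.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Default 64^3 cochlea phantom, shared across tests (read-only)."""
    return build_cochlea_phantom(PhantomParams(grid_size=64, voxel_um=5.0, seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
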