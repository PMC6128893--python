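import numpy as np
import pytest

from corrmicro import effective_geometry, make_cell_phantom


@pytest.fixture(scope="session")
def geom512():
    """Cone-beam geometry alias-safe for 512^2 grids (p_eff ~ 158 nm)."""
    return effective_geometry(125.0, 5000.0, 6.5, 13.8)


@pytest.fixture(scope="session")
def geom256():
    """Cone-beam geometry alias-safe for 256^2 grids (p_eff ~ 425 nm)."""
    return effective_geometry(350.0, 5000.0, 6.5, 13.8)


@pytest.fixture(scope="session")
def small_phantom():
    return make_cell_phantom(shape=(256, 256), pixel_size=40.0, seed=1)


@pytest.fixture()
def disc_phase_512():
    """Soft-edged disc phase object (phi = -0.5 inside, radius 60 px)."""
    n = 512
    zz, yy = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
    r = np.hypot(zz, yy)
    return -0.5 * np.clip(60.5 - r, 0.0, 1.0)
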