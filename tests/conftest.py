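import numpy as np
import pytest

from bootpet.phantom import PhantomSpec, make_phantom, simulate_acquisition, thin_counts
from bootpet.projector import Geometry, build_system


@pytest.fixture(scope="session")
def small_geom():
    # 32x32 at 4 mm keeps the whole head (incl. background) in a cheap grid
    return Geometry(
        n_angles=24, n_bins=47, bin_spacing_mm=4.0,
        image_shape=(32, 32), voxel_spacing_mm=(4.0, 4.0),
    )


@pytest.fixture(scope="session")
def small_system(small_geom):
    return build_system(small_geom, psf_fwhm_mm=2.5)


@pytest.fixture(scope="session")
def small_system_nopsf(small_geom):
    return build_system(small_geom, psf_fwhm_mm=0.0)


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(PhantomSpec(grid_shape=(32, 32), spacing_mm=(4.0, 4.0)), seed=0)


@pytest.fixture(scope="session")
def small_sino(small_phantom, small_system):
    return simulate_acquisition(small_phantom.activity, small_system, 500_000, seed=11)


@pytest.fixture(scope="session")
def small_sino_thinned(small_sino):
    return thin_counts(small_sino, 0.05, seed=13)


@pytest.fixture(scope="session")
def geom64():
    return Geometry()  # 60 angles x 95 bins, 64x64 at 2 mm


@pytest.fixture(scope="session")
def systems64(geom64):
    return {
        "mlem": build_system(geom64, 2.5),
        "mapem": build_system(geom64, 4.5),
    }


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom(PhantomSpec(), seed=0)


@pytest.fixture(scope="session")
def sino64(phantom64, systems64):
    return simulate_acquisition(
        phantom64.activity, systems64["mapem"], 2_000_000, seed=21
    )


@pytest.fixture(scope="session")
def sino64_thinned(sino64):
    return thin_counts(sino64, 0.05, seed=23)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
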