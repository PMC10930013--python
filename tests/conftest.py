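import numpy as np
import pytest

from cacdn import GridSpec, make_phantom_spec, simulate_scan


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def cirs_s():
    return make_phantom_spec("CIRS_S", 0)


@pytest.fixture(scope="session")
def qrm_s():
    return make_phantom_spec("QRM_S")


@pytest.fixture(scope="session")
def cirs_pair(cirs_s):
    """One simulated CIRS_S thin/3-mm pair at z = 1.5 mm."""
    return simulate_scan(cirs_s, z=1.5, seed=42)


def small_image(pixels, thickness=1.5, matrix=None, fov=None):
    """Wrap a raw array as a CTImage on a matching grid."""
    from cacdn import CTImage
    pixels = np.asarray(pixels, dtype=np.float32)
    n = pixels.shape[0]
    g = GridSpec(matrix=matrix or n, fov=fov or float(n))
    return CTImage(pixels=pixels, grid=g, slice_thickness=thickness,
                   tube_current=40.0)
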