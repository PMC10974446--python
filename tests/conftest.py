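import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from osmltr.geometry import ImageGrid, ScanGeometry, make_angle_list, partition_subsets
from osmltr.synthetic_phantom import (
    default_qrm_phantom,
    rasterize_phantom,
    simulate_projections,
)


@pytest.fixture(scope="session")
def small_grid():
    return ImageGrid(n=16, pixel_size=0.5)


@pytest.fixture(scope="session")
def small_geom():
    """Desk-scale fan-beam geometry whose fan comfortably covers the grid."""
    return ScanGeometry(
        sid=60.0, sod=30.0, n_det=24, det_pitch=1.0,
        angles_deg=tuple(make_angle_list(20)),
    )


@pytest.fixture(scope="session")
def small_subsets(small_geom):
    return partition_subsets(small_geom.n_views, 2)


@pytest.fixture(scope="session")
def small_phantom(small_grid):
    spec = default_qrm_phantom(small_grid)
    return spec, rasterize_phantom(spec)


@pytest.fixture(scope="session")
def small_projections(small_phantom, small_geom, small_grid):
    _, image = small_phantom
    return simulate_projections(image, small_geom, small_grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240318)
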