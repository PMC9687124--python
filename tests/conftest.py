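import numpy as np
import pytest

from palpsim.materials import default_cards
from palpsim.phantom import PhantomConfig, build_phantom, mesh_from_mask, smooth_surface, tag_roi


@pytest.fixture(scope="session")
def cards():
    return default_cards()


@pytest.fixture(scope="session")
def default_mesh():
    """The default phantom, smoothed and ROI-tagged (as the pipeline uses it)."""
    cfg = PhantomConfig()
    mesh = smooth_surface(build_phantom(cfg), cfg.smoothing_iterations)
    return tag_roi(mesh, cfg.roi_band_mm)


@pytest.fixture()
def flesh_block():
    """Small all-flesh voxel block (6x5x4 voxels of 6 mm)."""
    return mesh_from_mask(np.zeros((6, 5, 4), dtype=int), 6.0)


def small_phantom_config():
    """A reduced phantom with all three parts, cheap enough for dynamics tests."""
    return PhantomConfig(
        block_dims=(60.0, 48.0, 36.0),
        voxel_size=6.0,
        liver_center=(30.0, 21.0, 24.0),
        liver_semiaxes=(18.0, 10.0, 8.0),
        rib_count=2,
        rib_spacing=12.0,
        rib_radius=4.0,
        rib_first_y=31.0,
        rib_depth_z=31.0,
        roi_band_mm=12.0,
    )


@pytest.fixture(scope="session")
def small_phantom():
    cfg = small_phantom_config()
    return tag_roi(smooth_surface(build_phantom(cfg), 2), cfg.roi_band_mm)
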