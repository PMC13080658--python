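import numpy as np
import pytest

from bridgekit import BinaryMask, Volume


def make_cylinder_mask(
    radius_um: float,
    spacing: float = 5.0,
    length_vox: int = 40,
    half_width_vox: int | None = None,
    axis: int = 0,
) -> BinaryMask:
    """Binary cylinder along ``axis`` whose axis passes through voxel
    centers (so the discrete inscribed-sphere diameter equals the nominal
    one to within a voxel)."""
    if half_width_vox is None:
        half_width_vox = int(np.ceil(radius_um / spacing)) + 3
    width = 2 * half_width_vox + 1
    shape = [width, width, width]
    shape[axis] = length_vox
    grids = np.mgrid[: shape[0], : shape[1], : shape[2]]
    center = half_width_vox
    cross = [g for i, g in enumerate(grids) if i != axis]
    r2 = ((cross[0] - center) * spacing) ** 2 + ((cross[1] - center) * spacing) ** 2
    return BinaryMask(r2 <= radius_um**2 + 1e-9, (spacing,) * 3)


def make_sphere_mask(radius_um: float, spacing: float = 5.0) -> BinaryMask:
    half = int(np.ceil(radius_um / spacing)) + 3
    width = 2 * half + 1
    zz, yy, xx = np.mgrid[:width, :width, :width]
    r2 = (
        ((zz - half) * spacing) ** 2
        + ((yy - half) * spacing) ** 2
        + ((xx - half) * spacing) ** 2
    )
    return BinaryMask(r2 <= radius_um**2 + 1e-9, (spacing,) * 3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.normal(size=(8, 10, 12)), (10.0, 10.0, 10.0))
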