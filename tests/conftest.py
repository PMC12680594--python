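import numpy as np
import pytest

from fusvasc.core import ImageVolume, VesselNetwork


def cylinder_network(
    diameter_um: float,
    box_um=(30.0, 40.0, 40.0),
    center_yx=None,
    axis_points=2,
) -> VesselNetwork:
    """A single straight cylinder along z through the box centre."""
    bz, by, bx = box_um
    cy, cx = center_yx if center_yx is not None else (by / 2.0, bx / 2.0)
    z = np.linspace(0.0, bz, axis_points)
    pts = np.column_stack([z, np.full_like(z, cy), np.full_like(z, cx)])
    return VesselNetwork(
        segments=[(pts, diameter_um / 2.0)], box_um=(bz, by, bx)
    )


def cylinder_mask(
    diameter_um: float,
    shape=(16, 41, 41),
    spacing=(1.0, 1.0, 1.0),
    center_yx=None,
) -> ImageVolume:
    """Rasterized single cylinder along z (voxel-centre inclusion)."""
    nz, ny, nx = shape
    sy, sx = spacing[1], spacing[2]
    cy, cx = (
        center_yx
        if center_yx is not None
        else ((ny - 1) * sy / 2.0, (nx - 1) * sx / 2.0)
    )
    yy, xx = np.meshgrid(
        np.arange(ny) * sy, np.arange(nx) * sx, indexing="ij"
    )
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= (diameter_um / 2.0) ** 2
    mask = np.broadcast_to(disk, shape).copy()
    return ImageVolume(
        voxels=mask.astype(np.uint8), spacing_um=spacing, channel="label"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
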