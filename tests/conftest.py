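"""Shared fixtures: study-condition scenes generated once per session."""

import numpy as np
import pytest

from cytomap3d import synthgen as sg
from cytomap3d.grids import VoxelGrid
from cytomap3d.pipeline import extract_records
from cytomap3d.segment import SomaMask


@pytest.fixture(scope="session")
def fig4():
    """Rendered 631-cell giant/other mixture (286 giant + 345 other)."""
    return sg.make_fixture("fig4_mixture", sg.DEFAULT_SEED)


@pytest.fixture(scope="session")
def fig4_records(fig4):
    """Segmentation + basic features for every fig4 cell, seeded at truth centers."""
    centers = [c.center for c in fig4.cells]
    ids = [c.id for c in fig4.cells]
    records, failures = extract_records(fig4.grid, centers, ids, with_shape=False)
    return records, failures


@pytest.fixture(scope="session")
def betz():
    """Rendered 286-cell Betz shape fixture (93/45/118/30)."""
    return sg.make_fixture("betz_shapes", sg.DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_scene():
    """15 well-separated giant cells in a 160-μm cube (detection-scale)."""
    cells = sg.sample_population("giant_pyn", 15, seed=3)
    cells = sg.place_cells(cells, (160.0, 160.0, 160.0), min_sep=15.0, seed=4)
    grid, labels = sg.render_scene(cells, sg.RenderConfig(), (160.0, 160.0, 160.0), seed=5)
    return grid, labels, cells


def analytic_ellipsoid_mask(semi_axes_um, voxel_size=(1.0, 1.0, 1.0),
                            rotation=None, pad_um=3.0) -> SomaMask:
    """Independent oracle mask: voxelised ellipsoid from its analytic equation."""
    a = np.asarray(semi_axes_um, float)
    vs = np.asarray(voxel_size, float)
    bound = a.max() + pad_um
    n = np.ceil(2 * bound / vs).astype(int)
    center = n * vs / 2.0
    ii = [np.arange(n[k]) * vs[k] + 0.5 * vs[k] - center[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*ii, indexing="ij")
    pts = np.stack([gx, gy, gz])
    if rotation is not None:
        pts = np.einsum("ji,jabc->iabc", np.asarray(rotation), pts)
    mask = (pts[0] / a[0]) ** 2 + (pts[1] / a[1]) ** 2 + (pts[2] / a[2]) ** 2 <= 1.0
    return SomaMask(cell_id=1, mask=mask, origin_um=(0.0, 0.0, 0.0),
                    voxel_size=tuple(vs), seed_um=tuple(center))


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def noise_grid(shape=(60, 60, 60), level=200.0, sd=6.0, seed=0) -> VoxelGrid:
    rng = np.random.default_rng(seed)
    data = np.clip(level + rng.standard_normal(shape) * sd, 0, 255).astype(np.uint8)
    return VoxelGrid(data)
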