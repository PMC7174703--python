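"""Block store, cropping, projections, reslicing, illumination, downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytomap3d.grids import VoxelGrid
from cytomap3d import volstore as vo


def _random_grid(shape, seed=0, voxel=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    return VoxelGrid(rng.integers(0, 256, size=shape, dtype=np.uint8).astype(np.uint8),
                     voxel)


class TestBlockStore:
    def test_single_block_round_trip(self):
        g = _random_grid((100, 100, 100))
        store = vo.write_blocks(g, block_edge_um=100.0)
        assert store.grid_shape == (1, 1, 1)
        assert np.array_equal(vo.reassemble(store).data, g.data)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shape=st.tuples(*[st.integers(3, 40)] * 3),
        edge=st.integers(4, 30),
    )
    def test_round_trip_bitwise_property(self, shape, edge):
        g = _random_grid(shape, seed=sum(shape))
        store = vo.write_blocks(g, block_edge_um=float(edge))
        assert np.array_equal(vo.reassemble(store).data, g.data)

    def test_block_shape_anisotropic(self):
        # round(512 / 0.33) = 1552 at the full imaging resolution
        assert vo.block_shape_for((0.33, 0.33, 1.0), 512.0) == (1552, 1552, 512)
        assert vo.block_shape_for((1.0, 1.0, 1.0), 512.0) == (512, 512, 512)

    def test_read_block_origin_and_padding(self):
        g = _random_grid((30, 30, 30))
        store = vo.write_blocks(g, block_edge_um=20.0, fill_value=7)
        blk = vo.read_block(store, (1, 1, 1))
        assert blk.origin == (20.0, 20.0, 20.0)
        # the corner block holds 10 real voxels per axis, padding elsewhere
        assert np.array_equal(blk.data[:10, :10, :10], g.data[20:, 20:, 20:])
        assert (blk.data[10:] == 7).all()

    def test_read_block_out_of_range(self):
        g = _random_grid((10, 10, 10))
        store = vo.write_blocks(g, 10.0)
        with pytest.raises(IndexError):
            vo.read_block(store, (-1, 0, 0))
        with pytest.raises(IndexError):
            vo.read_block(store, (1, 0, 0))

    def test_disk_round_trip(self, tmp_path):
        g = _random_grid((25, 18, 12))
        store = vo.write_blocks(g, 10.0, root=tmp_path / "store")
        loaded = vo.BlockStore.load(tmp_path / "store")
        assert np.array_equal(vo.reassemble(loaded).data, g.data)
        assert loaded.voxel_size == store.voxel_size


class TestCropCube:
    def test_mid_volume_shape(self):
        g = _random_grid((200, 200, 200))
        cube = vo.crop_cube(g, (100.0, 100.0, 100.0), 128.0)
        assert cube.shape == (128, 128, 128)

    def test_corner_padded(self):
        g = _random_grid((200, 200, 200))
        cube = vo.crop_cube(g, (2.0, 2.0, 2.0), 128.0)
        assert cube.shape == (128, 128, 128)
        # the out-of-volume corner is constant fill
        assert len(np.unique(cube.data[:30, :30, :30])) == 1

    def test_anisotropic_shape(self):
        g = _random_grid((500, 500, 160), voxel=(0.33, 0.33, 1.0))
        cube = vo.crop_cube(g, (80.0, 80.0, 80.0), 128.0)
        assert cube.shape == (388, 388, 128)

    def test_center_outside_raises(self):
        g = _random_grid((50, 50, 50))
        with pytest.raises(ValueError):
            vo.crop_cube(g, (60.0, 10.0, 10.0), 16.0)

    def test_nested_crop_equals_direct(self):
        g = _random_grid((120, 120, 120))
        outer = vo.crop_cube(g, (60.0, 60.0, 60.0), 80.0)
        inner_via_outer = vo.crop_cube(outer, (55.0, 58.0, 61.0), 24.0)
        direct = vo.crop_cube(g, (55.0, 58.0, 61.0), 24.0)
        assert np.array_equal(inner_via_outer.data, direct.data)
        assert inner_via_outer.origin == direct.origin

    def test_crop_from_block_store_matches_grid(self):
        g = _random_grid((90, 90, 90))
        store = vo.write_blocks(g, 32.0)
        a = vo.crop_cube(store, (45.0, 45.0, 45.0), 40.0)
        b = vo.crop_cube(g, (45.0, 45.0, 45.0), 40.0)
        assert np.array_equal(a.data, b.data)


class TestMip:
    def test_constant_volume(self):
        g = VoxelGrid(np.full((20, 20, 20), 77, dtype=np.uint8))
        img = vo.mip(g, "z", depth_um=20.0)
        assert (img == 77).all()

    def test_extreme_voxel_carried(self):
        data = np.full((30, 30, 30), 200, dtype=np.uint8)
        data[7, 11, 4] = 10  # dark_cells: minimum projection carries it
        g = VoxelGrid(data)
        img = vo.mip(g, "z", depth_um=20.0, position_um=0.0)
        assert img[7, 11] == 10

    def test_slab_depth_in_sections(self):
        data = np.full((10, 10, 40), 200, dtype=np.uint8)
        data[5, 5, 25] = 10
        g = VoxelGrid(data)
        # 20-μm slab over 1-μm sections reduces over exactly 20 sections
        img0 = vo.mip(g, "z", 20.0, position_um=0.0)
        img1 = vo.mip(g, "z", 20.0, position_um=20.0)
        assert img0[5, 5] == 200 and img1[5, 5] == 10

    def test_mip_idempotent_depth_one(self):
        g = _random_grid((15, 15, 15))
        assert np.array_equal(vo.mip(g, "z", 1.0, 4.0), g.data[:, :, 4])

    def test_monotone_in_depth_bright(self):
        g = _random_grid((20, 20, 20))
        a = vo.mip(g, "z", 5.0, 0.0, polarity="bright_cells")
        b = vo.mip(g, "z", 15.0, 0.0, polarity="bright_cells")
        assert (b >= a).all()

    def test_slab_outside_raises(self):
        g = _random_grid((10, 10, 10))
        with pytest.raises(ValueError):
            vo.mip(g, "z", 20.0, position_um=5.0)


class TestReslice:
    def test_horizontal_identity_section(self):
        g = _random_grid((25, 25, 25))
        img = vo.reslice(g, "horizontal", position_um=10.0, thickness_um=1.0)
        assert np.array_equal(img, g.data[:, :, 10])

    def test_anisotropic_square_pixels(self):
        # ramp along z with 2-μm sections; sagittal output must be isotropic
        data = np.tile(np.arange(20, dtype=np.uint8) * 10, (30, 40, 1))
        g = VoxelGrid(data, voxel_size=(1.0, 1.0, 2.0))
        img = vo.reslice(g, "sagittal", position_um=15.0, thickness_um=2.0)
        assert img.shape == (40, 40)  # 40 μm × (20 vox × 2 μm) at 1 μm pixels
        # linear-interpolation oracle: values increase monotonically along z
        col = img[5]
        assert (np.diff(col) >= -1e-3).all()
        assert abs(float(col[0]) - 0.0) < 10 and abs(float(col[-1]) - 190.0) < 10

    def test_thickness_20um_slab(self):
        data = np.full((10, 10, 40), 200, dtype=np.uint8)
        data[3, 3, 19] = 10
        g = VoxelGrid(data)
        img = vo.reslice(g, "horizontal", position_um=0.0, thickness_um=20.0)
        assert img[3, 3] == 10  # dark extreme inside the 20-section slab

    def test_unknown_plane(self):
        with pytest.raises(ValueError):
            vo.reslice(_random_grid((5, 5, 5)), "axial", 0.0)


class TestIlluminationCorrection:
    def test_uniform_unchanged(self):
        img = np.full((40, 60), 150.0)
        out = vo.correct_illumination(img)
        assert np.abs(out - 150.0).max() < 1.0

    def test_linear_gain_flattened(self):
        # flat scene times a 0.8 -> 1.2 column gain recovers flat within 2%
        gain = np.linspace(0.8, 1.2, 200)
        img = np.full((80, 200), 150.0) * gain[None, :]
        out = vo.correct_illumination(img, axis=1)
        assert np.abs(out - 150.0).max() / 150.0 < 0.02

    def test_zero_column_guarded(self):
        img = np.full((30, 30), 100.0)
        img[:, 4] = 0.0
        out = vo.correct_illumination(img)
        assert np.isfinite(out).all()


class TestDownsample:
    def test_identity_at_source_resolution(self):
        g = _random_grid((12, 12, 12))
        out = vo.downsample(g, 1.0)
        assert np.array_equal(out.data, g.data.astype(np.float32))

    def test_constant_stays_constant(self):
        g = VoxelGrid(np.full((40, 40, 40), 9, dtype=np.uint8))
        out = vo.downsample(g, 20.0)
        assert np.allclose(out.data, 9.0)
        assert out.voxel_size == (20.0, 20.0, 20.0)

    def test_pooling_window_20um(self):
        g = VoxelGrid(np.arange(40 * 40 * 40, dtype=np.float32).reshape(40, 40, 40) % 251)
        out = vo.downsample(g, 20.0)
        assert out.shape == (2, 2, 2)
        # mean-pool oracle on one window
        assert np.isclose(out.data[0, 0, 0], g.data[:20, :20, :20].mean())

    def test_target_smaller_than_source_raises(self):
        g = _random_grid((10, 10, 10), voxel=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError):
            vo.downsample(g, 1.0)
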