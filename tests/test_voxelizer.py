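import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from enzyvox.structure_io import BackboneTrace
from enzyvox.synthetic_fixtures import FixtureSpec, generate_trace
from enzyvox.voxelizer import (
    FlipCode,
    IDENTITY_FLIP,
    VoxelGrid,
    VoxelizerConfig,
    apply_flip,
    coords_to_grid,
    enumerate_flip_codes,
    homothety_ratio,
    interpolate_backbone,
    pca_orient,
    read_grid_cache,
    remove_isolated_voxels,
    voxelize,
    write_grid_cache,
)


class TestInterpolation:
    def test_p_zero_is_identity(self, rng):
        coords = rng.uniform(-5, 5, (7, 3))
        assert np.array_equal(interpolate_backbone(coords, 0), coords)

    def test_midpoint(self):
        out = interpolate_backbone(np.array([[0.0, 0, 0], [2, 2, 2]]), 1)
        assert np.allclose(out, [[0, 0, 0], [1, 1, 1], [2, 2, 2]])

    def test_five_point_segment(self):
        out = interpolate_backbone(np.array([[0.0, 0, 0], [6, 0, 0]]), 5)
        expected = [[k, 0, 0] for k in range(7)]
        assert np.allclose(out, expected)

    @pytest.mark.parametrize("n,p", [(2, 3), (5, 0), (4, 7), (10, 2)])
    def test_output_length(self, n, p, rng):
        out = interpolate_backbone(rng.uniform(-3, 3, (n, 3)), p)
        assert out.shape == (n + (n - 1) * p, 3)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            interpolate_backbone(np.zeros((2, 3)), -1)


class TestHomothety:
    @pytest.mark.parametrize("l,r_max,expected",
                             [(32, 40, 0.375), (64, 40, 0.775), (4, 1, 1.0)])
    def test_ratio(self, l, r_max, expected):
        assert homothety_ratio(l, r_max) == pytest.approx(expected, abs=0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            homothety_ratio(2, 40)
        with pytest.raises(ValueError):
            homothety_ratio(32, 0)


class TestPcaOrient:
    def test_collinear_cloud_maps_to_first_axis(self):
        t = np.linspace(-1, 1, 20)
        coords = np.column_stack([t, t, np.zeros_like(t)])
        out = pca_orient(coords)
        assert np.allclose(out[:, 1:], 0.0, atol=1e-9)
        assert np.std(out[:, 0]) > 0

    def test_output_covariance_diagonal_descending(self, rng):
        coords = rng.standard_normal((500, 3)) * np.array([3.0, 1.0, 0.2])
        coords = coords - coords.mean(axis=0)
        out = pca_orient(coords)
        cov = out.T @ out / len(out)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8 * np.trace(cov)
        d = np.diag(cov)
        assert d[0] >= d[1] >= d[2]

    def test_recovers_generating_scales(self, rng):
        scales = np.array([10.0, 5.0, 1.0])
        cloud = rng.standard_normal((4000, 3)) * scales
        cloud = cloud - cloud.mean(axis=0)
        rot = Rotation.random(random_state=3).as_matrix()
        out = pca_orient(cloud @ rot.T)
        assert np.allclose(out.std(axis=0), scales, rtol=0.1)

    def test_scale_invariance(self, rng):
        coords = rng.standard_normal((50, 3)) * np.array([4.0, 2.0, 1.0])
        coords = coords - coords.mean(axis=0)
        assert np.allclose(pca_orient(3.5 * coords), 3.5 * pca_orient(coords),
                           atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pca_orient(np.zeros((1, 3)))

    def test_degenerate_cloud_warns(self):
        t = np.linspace(-1, 1, 10)
        coords = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        with pytest.warns(UserWarning, match="rank-deficient"):
            pca_orient(coords)


class TestFlips:
    def test_enumeration(self):
        all_codes = enumerate_flip_codes()
        assert len(all_codes) == 8
        assert len(set(all_codes)) == 8
        assert IDENTITY_FLIP in all_codes
        assert len(enumerate_flip_codes(include_identity=False)) == 7

    def test_identity_and_involution(self, rng):
        coords = rng.uniform(-3, 3, (10, 3))
        assert np.array_equal(apply_flip(coords, IDENTITY_FLIP), coords)
        for f in enumerate_flip_codes():
            assert np.allclose(apply_flip(apply_flip(coords, f), f), coords)

    def test_example(self):
        out = apply_flip(np.array([[1.0, 2.0, 3.0]]), FlipCode(1, 0, 1))
        assert np.allclose(out, [[-1.0, 2.0, -3.0]])

    def test_invalid_component(self):
        with pytest.raises(ValueError):
            FlipCode(2, 0, 0)


class TestCoordsToGrid:
    def test_single_point_at_center(self):
        grid = coords_to_grid(np.zeros((1, 3)), 32)
        assert grid.occupancy == 1
        assert grid.values[16, 16, 16] == 1

    def test_nearby_points_merge(self):
        grid = coords_to_grid(np.array([[0.1, 0.1, 0.1], [0.3, 0.2, 0.1]]), 32)
        assert grid.occupancy == 1

    def test_out_of_cube_point_discarded(self):
        with pytest.warns(UserWarning, match="outside"):
            grid = coords_to_grid(np.array([[20.0, 0.0, 0.0]]), 32)
        assert grid.occupancy == 0


class TestRemoveIsolated:
    def test_lone_voxel_removed(self):
        values = np.zeros((8, 8, 8), dtype=np.uint8)
        values[4, 4, 4] = 1
        out = remove_isolated_voxels(VoxelGrid(values, 8))
        assert out.occupancy == 0

    def test_adjacent_pair_kept(self):
        values = np.zeros((8, 8, 8), dtype=np.uint8)
        values[4, 4, 4] = values[4, 4, 5] = 1
        out = remove_isolated_voxels(VoxelGrid(values, 8))
        assert out.occupancy == 2

    def test_distant_voxel_removed_run_kept(self):
        # 3-voxel run plus one voxel at Chebyshev distance 2 from the run
        values = np.zeros((10, 10, 10), dtype=np.uint8)
        values[3, 5, 5] = values[4, 5, 5] = values[5, 5, 5] = 1
        values[7, 5, 5] = 1
        out = remove_isolated_voxels(VoxelGrid(values, 10), connectivity=26)
        assert out.values[7, 5, 5] == 0
        assert out.values[3, 5, 5] == out.values[4, 5, 5] == out.values[5, 5, 5] == 1

    def test_connectivity_6_vs_26_on_diagonal_pair(self):
        values = np.zeros((8, 8, 8), dtype=np.uint8)
        values[4, 4, 4] = values[5, 5, 5] = 1  # corner-adjacent only
        assert remove_isolated_voxels(VoxelGrid(values, 8), 26).occupancy == 2
        assert remove_isolated_voxels(VoxelGrid(values, 8), 6).occupancy == 0

    def test_monotone_decreasing(self, rng):
        values = (rng.random((16, 16, 16)) < 0.03).astype(np.uint8)
        out = remove_isolated_voxels(VoxelGrid(values, 16))
        assert np.all(out.values <= values)


def _rotated(trace: BackboneTrace, seed: int) -> BackboneTrace:
    rot = Rotation.random(random_state=seed).as_matrix()
    return BackboneTrace(trace.structure_id, trace.residue_indices,
                         trace.atom_names, trace.coords @ rot.T)


class TestVoxelizePipeline:
    def test_straight_chain_contiguous_run_on_first_axis(self, vox_cfg):
        trace = generate_trace(FixtureSpec("straight", n_residues=10,
                                           scale=20.0, noise_sd=0.0, seed=1))
        grid = voxelize(trace, vox_cfg)
        occ = np.argwhere(grid.values)
        # PCA puts the chain on axis 1; the other two axes collapse to center
        assert np.all(occ[:, 1] == 16)
        assert np.all(occ[:, 2] == 16)
        runs = np.sort(occ[:, 0])
        assert np.all(np.diff(runs) == 1)
        assert runs[0] <= 16 <= runs[-1]

    def test_binary_shape_and_index_range(self, helix_trace, vox_cfg):
        grid = voxelize(helix_trace, vox_cfg)
        assert grid.values.shape == (32, 32, 32)
        assert set(np.unique(grid.values)) <= {0, 1}
        occ = np.argwhere(grid.values)
        assert occ.min() >= 1 and occ.max() <= 30

    def test_deterministic(self, helix_trace, vox_cfg):
        g1 = voxelize(helix_trace, vox_cfg)
        g2 = voxelize(helix_trace, vox_cfg)
        assert np.array_equal(g1.values, g2.values)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rotation_invariance(self, helix_trace, vox_cfg, seed):
        g1 = voxelize(helix_trace, vox_cfg)
        g2 = voxelize(_rotated(helix_trace, seed), vox_cfg)
        assert np.array_equal(g1.values, g2.values)

    @pytest.mark.parametrize("f", [FlipCode(1, 0, 0), FlipCode(0, 1, 1),
                                   FlipCode(1, 1, 1)])
    def test_flip_produces_mirror_grid(self, helix_trace, vox_cfg, f):
        base = voxelize(helix_trace, vox_cfg)
        flipped = voxelize(helix_trace, vox_cfg, f)
        l = vox_cfg.l
        occ = np.argwhere(base.values)
        mirror = occ.copy()
        for axis, d in enumerate(f.as_tuple()):
            if d:
                mirror[:, axis] = l - occ[:, axis]
        expected = np.zeros_like(base.values)
        expected[mirror[:, 0], mirror[:, 1], mirror[:, 2]] = 1
        assert np.array_equal(flipped.values, expected)

    def test_oversized_structure_is_clipped_not_failed(self, vox_cfg):
        trace = generate_trace(FixtureSpec("straight", n_residues=40,
                                           scale=120.0, noise_sd=0.0, seed=2))
        grid = voxelize(trace, vox_cfg)
        occ = np.argwhere(grid.values)
        assert grid.occupancy > 0
        assert occ.min() >= 1 and occ.max() <= 30


class TestConfig:
    @pytest.mark.parametrize("l,expected_p", [(32, 0), (64, 5), (96, 9)])
    def test_default_interpolation_by_grid_size(self, l, expected_p):
        assert VoxelizerConfig(l=l).interpolation == expected_p

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            VoxelizerConfig(l=31)
        with pytest.raises(ValueError):
            VoxelizerConfig(r_max=-1)
        with pytest.raises(ValueError):
            VoxelizerConfig(neighbor_connectivity=7)


def test_grid_cache_roundtrip(tmp_path, helix_trace, vox_cfg):
    grid = voxelize(helix_trace, vox_cfg)
    path = tmp_path / "grids.h5"
    write_grid_cache(path, [grid], vox_cfg)
    back = read_grid_cache(path)
    assert set(back) == {helix_trace.structure_id}
    assert np.array_equal(back[helix_trace.structure_id].values, grid.values)
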