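"""Displacement-field computation against explicit homogeneous-coordinate
oracles, plus the FD/RD/dRD aggregation identities."""

import numpy as np
import pytest

from conftest import make_series, random_rigid, simple_atlas

from rdiconn.motionfield import (
    DisplacementField,
    RigidMotionSeries,
    delta_rd,
    frame_displacement,
    load_par_file,
    load_rigid_transforms,
    matrix_to_params,
    motion_summary,
    params_to_matrix,
    reexpress_about_origin,
    regional_displacement,
    voxelwise_displacement,
)


def oracle_displacement(mats, mask, affine):
    """Brute-force per-voxel displacement derivative via explicit
    homogeneous-coordinate multiplication, voxel by voxel."""
    T = len(mats)
    voxels = np.argwhere(mask)
    out = np.zeros((len(voxels), T))
    for v, ijk in enumerate(voxels):
        x = affine @ np.array([*ijk, 1.0])
        dist = np.empty(T)
        for t in range(T):
            y = np.linalg.inv(mats[t]) @ x
            dist[t] = np.sqrt(((y[:3] - x[:3]) ** 2).sum())
        out[v, 1:] = np.abs(np.diff(dist))
    return out


class TestLoading:
    def test_identity_files_give_identity_series(self, tmp_path):
        for t in range(4):
            np.savetxt(tmp_path / f"MAT_{t:04d}", np.eye(4))
        paths = sorted(tmp_path.iterdir())
        series = load_rigid_transforms(paths, np.eye(4), reference_index=0)
        assert np.allclose(series.transforms, np.eye(4))

    def test_translation_file_round_trips(self, tmp_path):
        M = np.eye(4)
        M[:3, 3] = [3.0, 0.0, 0.0]
        np.savetxt(tmp_path / "MAT_0000", np.eye(4))
        np.savetxt(tmp_path / "MAT_0001", M)
        series = load_rigid_transforms(
            sorted(tmp_path.iterdir()), np.eye(4), reference_index=0)
        assert np.allclose(series.transforms[1][:3, 3], [3.0, 0.0, 0.0])

    def test_center_reexpression_maps_points_identically(self, rng):
        """A rotation about the image centre, re-expressed about the world
        origin, must send every world point to the same image."""
        center = np.array([10.0, -4.0, 7.0])
        M = random_rigid(rng, max_angle=0.3)
        W = reexpress_about_origin(M, center)
        for _ in range(20):
            x = rng.uniform(-30, 30, 3)
            via_center = M[:3, :3] @ (x - center) + M[:3, 3] + center
            via_origin = W[:3, :3] @ x + W[:3, 3]
            assert np.allclose(via_center, via_origin, atol=1e-10)

    def test_non_rigid_matrix_rejected(self, tmp_path):
        bad = np.eye(4)
        bad[0, 0] = 2.0  # scaling, not rigid
        np.savetxt(tmp_path / "MAT_0000", bad)
        np.savetxt(tmp_path / "MAT_0001", np.eye(4))
        with pytest.raises(ValueError, match="invalid transform"):
            load_rigid_transforms(sorted(tmp_path.iterdir()), np.eye(4))

    def test_frame_count_mismatch_rejected(self, tmp_path):
        for t in range(3):
            np.savetxt(tmp_path / f"MAT_{t:04d}", np.eye(4))
        with pytest.raises(ValueError, match="length mismatch"):
            load_rigid_transforms(sorted(tmp_path.iterdir()), np.eye(4),
                                  n_frames_expected=5)

    def test_par_file_matches_matrix_construction(self, tmp_path, rng):
        params = rng.normal(0, 0.02, size=(5, 6))
        np.savetxt(tmp_path / "motion.par", params)
        series = load_par_file(tmp_path / "motion.par", np.eye(4),
                               reference_index=0)
        expect = params_to_matrix(params[2]) @ np.linalg.inv(
            params_to_matrix(params[0]))
        assert np.allclose(series.transforms[2], expect, atol=1e-10)

    def test_params_matrix_round_trip(self, rng):
        p = rng.normal(0, 0.1, 6)
        assert np.allclose(matrix_to_params(params_to_matrix(p)), p, atol=1e-10)


class TestVoxelwiseDisplacement:
    def test_identity_series_gives_zero_field(self):
        series = make_series([np.eye(4)] * 3)
        mask = np.ones((4, 4, 4), bool)
        fld = voxelwise_displacement(series, mask)
        assert np.allclose(fld.data, 0.0)

    def test_pure_translation_is_spatially_constant(self):
        M = np.eye(4)
        M[:3, 3] = [3.0, 0.0, 0.0]
        series = make_series([np.eye(4), M, np.eye(4)])
        mask = np.ones((4, 4, 4), bool)
        fld = voxelwise_displacement(series, mask)
        assert np.allclose(fld.data[..., 1], 3.0)
        assert np.allclose(fld.data[..., 2], 3.0)  # back to reference
        assert np.allclose(fld.data[..., 0], 0.0)

    def test_rotation_matches_chord_length_formula(self):
        """Rotation by theta about the z-axis displaces a voxel at distance r
        from the axis by 2 r sin(theta/2)."""
        theta = 0.02
        c, s = np.cos(theta), np.sin(theta)
        M = np.eye(4)
        M[:3, :3] = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
        series = make_series([np.eye(4), M])
        mask = np.zeros((60, 1, 1), bool)
        mask[50, 0, 0] = True  # world position (50, 0, 0)
        fld = voxelwise_displacement(series, mask)
        expected = 2 * 50 * np.sin(theta / 2)
        assert np.isclose(fld.masked_series()[0, 1], expected, atol=1e-8)

    def test_rotation_displacement_linear_in_axis_distance(self):
        theta = 0.05
        c, s = np.cos(theta), np.sin(theta)
        M = np.eye(4)
        M[:3, :3] = [[c, -s, 0], [s, c, 0], [0, 0, 1]]
        series = make_series([np.eye(4), M])
        mask = np.ones((40, 1, 1), bool)
        fld = voxelwise_displacement(series, mask)
        d = fld.masked_series()[:, 1]
        radii = np.arange(40.0)
        slope = 2 * np.sin(theta / 2)
        assert np.allclose(d, slope * radii, atol=1e-10)

    def test_random_rigid_series_matches_point_mapping_oracle(self, rng):
        mats = [np.eye(4)] + [random_rigid(rng) for _ in range(5)]
        affine = np.eye(4)
        affine[:3, 3] = [-3, -3, -3]
        series = make_series(mats, affine=affine)
        mask = rng.random((6, 6, 6)) > 0.4
        fld = voxelwise_displacement(series, mask)
        expect = oracle_displacement(series.transforms, mask, affine)
        assert np.allclose(fld.masked_series(), expect, atol=1e-10)

    def test_rms_norm_scales_by_sqrt3(self, rng):
        series = make_series([np.eye(4), random_rigid(rng)])
        mask = np.ones((3, 3, 3), bool)
        eu = voxelwise_displacement(series, mask, norm="euclidean")
        rm = voxelwise_displacement(series, mask, norm="rms")
        assert np.allclose(eu.data / np.sqrt(3), rm.data, atol=1e-12)

    def test_empty_mask_rejected(self):
        series = make_series([np.eye(4), np.eye(4)])
        with pytest.raises(ValueError, match="empty mask"):
            voxelwise_displacement(series, np.zeros((3, 3, 3), bool))

    def test_signed_derivative_restores_sign(self):
        M = np.eye(4)
        M[:3, 3] = [2.0, 0.0, 0.0]
        series = make_series([np.eye(4), M, np.eye(4)])
        mask = np.ones((2, 2, 2), bool)
        signed = voxelwise_displacement(series, mask, signed_derivative=True)
        assert np.allclose(signed.data[..., 1], 2.0)
        assert np.allclose(signed.data[..., 2], -2.0)


class TestSummaries:
    @pytest.fixture()
    def random_field(self, rng):
        data = np.abs(rng.normal(size=(5, 5, 5, 7)))
        data[..., 0] = 0.0
        mask = rng.random((5, 5, 5)) > 0.3
        data[~mask] = 0.0
        return DisplacementField(data, np.eye(4), mask)

    def test_fd_matches_bruteforce_mean(self, random_field):
        fd = frame_displacement(random_field)
        for t in range(random_field.n_frames):
            vals = [random_field.data[i, j, k, t]
                    for i, j, k in np.argwhere(random_field.mask)]
            assert np.isclose(fd[t], np.mean(vals), atol=1e-12)

    def test_whole_mask_region_rd_equals_fd(self, random_field):
        atlas = simple_atlas(random_field.mask.astype(int))
        rd = regional_displacement(random_field, atlas)
        fd = frame_displacement(random_field)
        assert np.allclose(rd[0], fd, atol=1e-10)

    def test_rd_matches_per_region_bruteforce(self, random_field, rng):
        labels = np.zeros(random_field.mask.shape, int)
        labels[random_field.mask] = rng.integers(1, 6,
                                                 random_field.mask.sum())
        # ensure all 5 regions present
        labels[random_field.mask] = np.resize(np.arange(1, 6),
                                              random_field.mask.sum())
        atlas = simple_atlas(labels)
        rd = regional_displacement(random_field, atlas)
        series = random_field.masked_series()
        lab = labels[random_field.mask]
        for i, rid in enumerate(atlas.region_ids):
            assert np.allclose(rd[i], series[lab == rid].mean(axis=0),
                               atol=1e-12)

    def test_voxel_count_weighted_rd_recovers_fd(self, random_field):
        labels = np.zeros(random_field.mask.shape, int)
        labels[random_field.mask] = np.resize(np.arange(1, 4),
                                              random_field.mask.sum())
        atlas = simple_atlas(labels)
        rd = regional_displacement(random_field, atlas)
        counts = np.array([(labels == r).sum() for r in atlas.region_ids])
        fd = frame_displacement(random_field)
        weighted = (rd * counts[:, None]).sum(axis=0) / counts.sum()
        assert np.allclose(weighted, fd, atol=1e-10)

    def test_delta_rd_identities(self, rng):
        fd = np.abs(rng.normal(size=10))
        rd = np.vstack([fd, fd + 0.01, np.abs(rng.normal(size=10))])
        drd = delta_rd(rd, fd)
        assert np.isclose(drd[0], 0.0, atol=1e-12)
        assert np.isclose(drd[1], 0.01, atol=1e-12)
        assert np.isclose(drd[2], (rd[2] - fd).mean(), atol=1e-12)

    def test_delta_rd_weighted_sum_zero_over_partition(self, random_field):
        labels = np.zeros(random_field.mask.shape, int)
        labels[random_field.mask] = np.resize(np.arange(1, 4),
                                              random_field.mask.sum())
        atlas = simple_atlas(labels)
        rd = regional_displacement(random_field, atlas)
        fd = frame_displacement(random_field)
        drd = delta_rd(rd, fd)
        counts = np.array([(labels == r).sum() for r in atlas.region_ids])
        assert np.isclose((drd * counts).sum() / counts.sum(), 0.0, atol=1e-10)

    def test_delta_rd_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            delta_rd(np.zeros((2, 5)), np.zeros(4))

    def test_motion_summary_bundles_consistently(self, random_field):
        atlas = simple_atlas(random_field.mask.astype(int))
        summ = motion_summary(random_field, atlas)
        assert np.isclose(summ.mean_fd, summ.fd[1:].mean())
        assert summ.mean_voxel_map.shape == random_field.mask.shape
        assert np.allclose(summ.delta_rd, 0.0, atol=1e-10)
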