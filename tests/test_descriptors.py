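"""Normal estimation and the four shape descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from shapeclust.descriptors3d import (DescriptorConfig, estimate_normals,
                                      fpfh, pair_features, rsd,
                                      sc_point_weight, shape_context_3d,
                                      spfh, vfh)
from shapeclust.pdb_io import PointCloud


def _rotate(vecs, rotvec):
    return vecs @ Rotation.from_rotvec(rotvec).as_matrix().T


class TestEstimateNormals:
    def test_plane_gives_z_normals(self, plane_cloud):
        cloud = estimate_normals(plane_cloud, neighbor_k=8,
                                 viewpoint=np.array([0.0, 0.0, 100.0]))
        np.testing.assert_allclose(np.abs(cloud.normals[:, 2]), 1.0, atol=1e-9)
        # consistently oriented toward the viewpoint
        assert np.all(cloud.normals[:, 2] > 0)

    def test_sphere_normals_near_radial(self, sphere_cloud):
        cloud = estimate_normals(
            PointCloud(points=sphere_cloud.points), neighbor_k=10,
            viewpoint=np.array([0.0, 0.0, 100.0]))
        radial = sphere_cloud.points / 5.0
        cos = np.abs(np.sum(cloud.normals * radial, axis=1))
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert np.percentile(angles, 95) < 10.0

    def test_too_few_points_errors(self):
        cloud = PointCloud(points=np.array([[0.0, 0, 0], [1, 0, 0]]))
        with pytest.raises(ValueError, match="neighbor_k"):
            estimate_normals(cloud, neighbor_k=5)

    def test_deterministic(self, plane_cloud):
        a = estimate_normals(plane_cloud, 8)
        b = estimate_normals(plane_cloud, 8)
        np.testing.assert_array_equal(a.normals, b.normals)


class TestPairFeatures:
    def test_perpendicular_normals_give_zero_triplet(self):
        alpha, phi, theta = pair_features(
            np.zeros(3), np.array([0.0, 0, 1]),
            np.array([1.0, 0, 0]), np.array([0.0, 0, 1]))
        assert (alpha, phi, theta) == pytest.approx((0.0, 0.0, 0.0))

    def test_flipped_second_normal_gives_pi_theta(self):
        alpha, phi, theta = pair_features(
            np.zeros(3), np.array([0.0, 0, 1]),
            np.array([1.0, 0, 0]), np.array([0.0, 0, -1]))
        assert (alpha, phi) == pytest.approx((0.0, 0.0))
        assert abs(theta) == pytest.approx(np.pi)

    def test_coincident_points_error(self):
        with pytest.raises(ValueError, match="coincident"):
            pair_features(np.zeros(3), np.array([0.0, 0, 1]),
                          np.zeros(3), np.array([0.0, 0, 1]))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p1, p2 = rng.normal(size=(2, 3))
        n1, n2 = rng.normal(size=(2, 3))
        n1 /= np.linalg.norm(n1)
        n2 /= np.linalg.norm(n2)
        base = pair_features(p1, n1, p2, n2)
        rv = rng.normal(size=3)
        shift = rng.normal(size=3)
        moved = pair_features(_rotate(p1, rv) + shift, _rotate(n1, rv),
                              _rotate(p2, rv) + shift, _rotate(n2, rv))
        assert moved == pytest.approx(base, abs=1e-9)


class TestSpfhFpfh:
    def test_coplanar_identical_normals_single_bin_per_feature(self):
        # neighbors in a ring around the query, all normals +z: every pair
        # feature triple is identical, so each block has one occupied bin
        pts = [np.zeros(3)] + [
            [np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 7)[:-1]
        ]
        cloud = PointCloud(points=np.array(pts),
                           normals=np.tile([0.0, 0, 1], (7, 1)))
        vec = spfh(cloud, 0, neighbor_k=6, bins_per_feature=11)
        for block in vec.reshape(3, 11):
            assert np.count_nonzero(block) == 1
            assert block.sum() == pytest.approx(100.0)

    def test_blocks_sum_to_100(self, sphere_cloud):
        vec = spfh(sphere_cloud, 17, neighbor_k=10)
        for block in vec.reshape(3, 11):
            assert block.sum() == pytest.approx(100.0, abs=1e-6)

    def test_default_dimensionality_is_33(self, sphere_cloud):
        assert spfh(sphere_cloud, 0, neighbor_k=5).shape == (33,)
        ds = fpfh(sphere_cloud, neighbor_k=5, anchors=np.arange(4))
        assert ds.vectors.shape == (4, 33)

    def test_symmetric_ring_doubles_spfh(self):
        # Regular octagon of unit side, normals +z: by symmetry every SPFH is
        # equal and both nearest neighbors sit at distance 1, so
        # FPFH = SPFH + (1/k) * sum SPFH/1 = 2 * SPFH.
        r = 1.0 / (2 * np.sin(np.pi / 8))
        ang = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(8)], axis=1)
        cloud = PointCloud(points=pts, normals=np.tile([0.0, 0, 1], (8, 1)))
        s0 = spfh(cloud, 0, neighbor_k=2)
        ds = fpfh(cloud, neighbor_k=2)
        np.testing.assert_allclose(ds.vectors[0], 2.0 * s0, atol=1e-9)

    def test_translation_invariance(self, sphere_cloud):
        cloud = sphere_cloud
        shifted = PointCloud(points=cloud.points + np.array([10.0, 0, 0]),
                             normals=cloud.normals.copy())
        a = fpfh(cloud, neighbor_k=8, anchors=np.arange(20))
        b = fpfh(shifted, neighbor_k=8, anchors=np.arange(20))
        assert np.abs(a.vectors - b.vectors).max() < 1e-9

    def test_missing_normals_error(self, plane_cloud):
        with pytest.raises(ValueError, match="no normals"):
            fpfh(plane_cloud)


class TestShapeContext:
    def test_point_weight_formula(self):
        assert sc_point_weight(1, 27.0) == pytest.approx(1 / 3)
        assert sc_point_weight(2, 27.0) == pytest.approx(1 / 6)

    def test_vector_length_is_bin_product(self, sphere_cloud):
        cfg = DescriptorConfig(sc_bins=(4, 2, 3))
        ds = shape_context_3d(sphere_cloud, cfg, anchors=np.arange(3))
        assert ds.vectors.shape == (3, 24)

    def test_mass_conservation(self):
        # With a single elevation and radial bin every bin has the same
        # volume V = (2 pi / J)(cos 0 - cos pi)(r_max^3 - r_min^3)/3, so the
        # total histogram mass is sum_j 1/(rho_j * V^(1/3)) — recomputed here
        # with plain distance arithmetic, independent of the implementation.
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 10, size=(60, 3))
        normals = rng.normal(size=(60, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        cloud = PointCloud(points=pts, normals=normals)
        r_max, delta, frac = 6.0, 2.5, 0.1
        cfg = DescriptorConfig(sc_bins=(4, 1, 1), support_radius=r_max,
                               sc_density_radius=delta,
                               sc_min_radius_fraction=frac)
        ds = shape_context_3d(cloud, cfg, anchors=np.array([5]))
        d_all = np.linalg.norm(pts - pts[5], axis=1)
        support = [j for j in range(60) if j != 5 and d_all[j] <= r_max]
        volume = (2 * np.pi / 4) * 2.0 * (r_max**3 - (frac * r_max) ** 3) / 3.0
        expected = sum(
            1.0 / (np.sum(np.linalg.norm(pts - pts[j], axis=1) <= delta)
                   * np.cbrt(volume))
            for j in support
        )
        assert ds.vectors[0].sum() == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(ds.vectors[0]) <= len(support)

    def test_empty_support_warns_and_zeroes(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [0, 100.0, 0],
                        [0, 0, 100.0]])
        normals = np.tile([0.0, 0, 1], (4, 1))
        cloud = PointCloud(points=pts, normals=normals)
        cfg = DescriptorConfig(sc_bins=(4, 2, 3), support_radius=5.0)
        with pytest.warns(UserWarning, match="empty 3DSC support"):
            ds = shape_context_3d(cloud, cfg, anchors=np.array([0]))
        assert np.all(ds.vectors == 0)


class TestRsd:
    def _two_point_cloud(self, d, alpha_deg):
        # anchor at origin, neighbor at distance d, normals opening alpha
        pts = np.array([[0.0, 0, 0], [d, 0.0, 0.0]])
        n0 = np.array([0.0, 0, 1.0])
        a = np.deg2rad(alpha_deg)
        n1 = np.array([np.sin(a), 0.0, np.cos(a)])
        return PointCloud(points=pts, normals=np.stack([n0, n1]))

    def test_exact_chord_inversion(self):
        # d = 2, alpha = 60 deg: r = d / sqrt(2 - 2 cos 60) = 2
        cloud = self._two_point_cloud(2.0, 60.0)
        ds = rsd(cloud, DescriptorConfig(support_radius=5.0),
                 anchors=np.array([0]))
        np.testing.assert_allclose(ds.vectors[0], [2.0, 2.0], atol=1e-9)

    def test_parallel_normals_clamp_to_plane_radius(self):
        cloud = self._two_point_cloud(2.0, 0.0)
        cfg = DescriptorConfig(support_radius=5.0, rsd_plane_radius=20.0)
        ds = rsd(cloud, cfg, anchors=np.array([0]))
        np.testing.assert_allclose(ds.vectors[0], [20.0, 20.0])

    def test_sphere_radius_recovered_within_5_percent(self, sphere_cloud):
        cfg = DescriptorConfig(support_radius=4.0)
        ds = rsd(sphere_cloud, cfg, anchors=np.arange(50))
        assert np.all(np.abs(ds.vectors - 5.0) / 5.0 < 0.05)

    def test_rmin_le_rmax_le_plane_radius(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 8, size=(80, 3))
        normals = rng.normal(size=(80, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        cloud = PointCloud(points=pts, normals=normals)
        cfg = DescriptorConfig(support_radius=5.0, rsd_plane_radius=20.0)
        ds = rsd(cloud, cfg)
        assert np.all(ds.vectors[:, 0] <= ds.vectors[:, 1] + 1e-12)
        assert np.all(ds.vectors <= 20.0 + 1e-12)

    def test_no_neighbors_warns_with_plane_radius(self):
        pts = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        cloud = PointCloud(points=pts, normals=np.tile([0.0, 0, 1], (2, 1)))
        cfg = DescriptorConfig(support_radius=5.0)
        with pytest.warns(UserWarning, match="no RSD neighbors"):
            ds = rsd(cloud, cfg, anchors=np.array([0]))
        np.testing.assert_allclose(ds.vectors[0], [20.0, 20.0])


class TestVfh:
    def test_identical_clouds_identical_vectors(self, sphere_cloud):
        vp = np.array([0.0, 0, 50.0])
        a = vfh(sphere_cloud, vp)
        b = vfh(sphere_cloud, vp)
        assert a.vectors.shape[0] == 1
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_scaling_about_centroid_keeps_viewpoint_block(self, sphere_cloud):
        vp = np.array([0.0, 0, 50.0])
        bins = 11
        base = vfh(sphere_cloud, vp, bins)
        centroid = sphere_cloud.points.mean(axis=0)
        scaled = PointCloud(
            points=centroid + 2.0 * (sphere_cloud.points - centroid),
            normals=sphere_cloud.normals.copy())
        big = vfh(scaled, vp, bins)
        np.testing.assert_allclose(base.vectors[0, -bins:],
                                   big.vectors[0, -bins:], atol=1e-9)

    def test_rotation_changes_descriptor(self, sphere_cloud):
        rng = np.random.default_rng(1)
        # use an asymmetric cloud: a random blob
        pts = rng.uniform(0, 5, size=(100, 3))
        normals = rng.normal(size=(100, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        cloud = PointCloud(points=pts, normals=normals)
        # rotate about x so the pose relative to the +z viewpoint changes
        vp = np.array([0.0, 0, 50.0])
        R = Rotation.from_rotvec([np.pi / 2, 0, 0]).as_matrix()
        rotated = PointCloud(points=pts @ R.T, normals=normals @ R.T)
        a = vfh(cloud, vp).vectors
        b = vfh(rotated, vp).vectors
        assert np.abs(a - b).max() > 1e-6

    def test_viewpoint_at_centroid_errors(self, sphere_cloud):
        centroid = sphere_cloud.points.mean(axis=0)
        with pytest.raises(ValueError, match="viewpoint"):
            vfh(sphere_cloud, centroid)
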