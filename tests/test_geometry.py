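import numpy as np
import pytest

from bovimetry.cloud import PointCloud
from bovimetry.errors import (DegeneratePoseError, ImpossibleSurfaceTypeError,
                              ParameterError)
from bovimetry.geometry import (AmbiguousFrameWarning, SurfaceType,
                                classify_surface_type, compute_centroid,
                                compute_covariance, mean_gaussian_curvature,
                                normal_curvature_euler, normalize_pose,
                                orientation_correct, pca_frame)
from bovimetry.synth import SceneConfig, sample_body


class TestCentroidCovariance:
    def test_centroid_triangle(self):
        c = compute_centroid(PointCloud([[0, 0, 0], [2, 0, 0], [1, 3, 0]]))
        np.testing.assert_allclose(c, [1, 1, 0])

    def test_centroid_single_point(self):
        np.testing.assert_allclose(
            compute_centroid(PointCloud([[3.0, -1.0, 2.0]])), [3, -1, 2])

    def test_centroid_matches_direct_sum(self, random_cloud):
        expected = sum(p for p in random_cloud.points) / len(random_cloud)
        np.testing.assert_allclose(compute_centroid(random_cloud), expected,
                                   atol=1e-12)

    def test_covariance_two_points(self):
        cov = compute_covariance(PointCloud([[1, 0, 0], [-1, 0, 0]]))
        np.testing.assert_allclose(cov, np.diag([1.0, 0, 0]))

    def test_covariance_identical_points(self):
        cov = compute_covariance(PointCloud(np.ones((5, 3))))
        np.testing.assert_allclose(cov, np.zeros((3, 3)))

    def test_covariance_matches_outer_product_sum(self, random_cloud):
        c = compute_centroid(random_cloud)
        expected = sum(np.outer(p - c, p - c) for p in random_cloud.points) \
            / len(random_cloud)
        np.testing.assert_allclose(compute_covariance(random_cloud), expected,
                                   atol=1e-12)


class TestPcaFrame:
    def test_diagonal_cov(self):
        frame = pca_frame(np.diag([4.0, 1.0, 0.25]), np.zeros(3))
        np.testing.assert_allclose(frame.eigenvalues, [4, 1, 0.25])
        for i in range(3):
            assert abs(abs(frame.axes[i, i]) - 1) < 1e-12

    def test_rotated_cov_recovers_axes(self, rng):
        from bovimetry.synth import _random_rotation
        R = _random_rotation(rng)
        cov = R @ np.diag([4.0, 1.0, 0.25]) @ R.T
        frame = pca_frame(cov, np.zeros(3))
        for i in range(3):
            assert abs(abs(frame.axes[i] @ R[:, i]) - 1) < 1e-6

    def test_right_handed(self, rng):
        from bovimetry.synth import _random_rotation
        R = _random_rotation(rng)
        cov = R @ np.diag([5.0, 2.0, 1.0]) @ R.T
        frame = pca_frame(cov, np.zeros(3))
        assert np.linalg.det(frame.axes) > 0

    def test_degenerate_warns(self):
        with pytest.warns(AmbiguousFrameWarning):
            frame = pca_frame(np.zeros((3, 3)), np.zeros(3))
        np.testing.assert_allclose(frame.eigenvalues, np.zeros(3), atol=1e-12)


class TestNormalizePose:
    @staticmethod
    def _ellipsoid(rng, semi=(4.0, 2.0, 1.0), n=2000):
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return u * np.array(semi)

    def test_extent_ordering_after_normalization(self, rng):
        from bovimetry.synth import _random_rotation
        pts = self._ellipsoid(rng) @ _random_rotation(rng).T + [5, -2, 1]
        out, _ = normalize_pose(PointCloud(pts))
        ext = out.points.max(axis=0) - out.points.min(axis=0)
        assert ext[0] > ext[1] > ext[2]
        assert out.frame_id == "normalized"

    def test_idempotent_up_to_signs(self, rng):
        pts = self._ellipsoid(rng)
        once, _ = normalize_pose(PointCloud(pts))
        twice, _ = normalize_pose(once)
        np.testing.assert_allclose(np.abs(twice.points), np.abs(once.points),
                                   atol=1e-9)

    def test_up_hint_aligns_height_axis(self, rng):
        from bovimetry.synth import _rot_y
        body = sample_body(SceneConfig(), rng)
        R = _rot_y(1.1)
        cloud = PointCloud(body @ R.T)
        up = R @ np.array([0.0, 1.0, 0.0])
        out, frame = normalize_pose(cloud, up_hint=up)
        np.testing.assert_allclose(frame.axes[1], up, atol=1e-12)

    def test_body_up_heuristic_without_hint(self, rng):
        # legs extend far below the torso's center of mass: without any
        # ground information the height axis must still point up
        body = sample_body(SceneConfig(), rng)
        out, _ = normalize_pose(PointCloud(body))
        y = out.points[:, 1]
        assert -y.min() > y.max()  # hooves below, back line above


class TestOrientationCorrect:
    def test_canonical_body_unchanged(self, rng):
        body = sample_body(SceneConfig(), rng)
        body = body - body.mean(axis=0)  # head on -x by construction
        out, mirrored = orientation_correct(PointCloud(body))
        assert not mirrored
        np.testing.assert_array_equal(out.points, body)

    def test_reversed_body_mirrored(self, rng):
        body = sample_body(SceneConfig(), rng)
        body = body - body.mean(axis=0)
        flipped = body * np.array([-1.0, 1.0, 1.0])
        out, mirrored = orientation_correct(PointCloud(flipped))
        assert mirrored
        # the withers (global height max) must end up on -x
        assert out.points[np.argmax(out.points[:, 1]), 0] < 0

    def test_involution_guard(self, rng):
        body = sample_body(SceneConfig(), rng)
        body = body - body.mean(axis=0)
        once, _ = orientation_correct(PointCloud(body))
        twice, mirrored = orientation_correct(once)
        assert not mirrored
        np.testing.assert_array_equal(once.points, twice.points)

    def test_mirror_applied_twice_is_identity(self):
        from bovimetry.geometry import MIRROR_X
        np.testing.assert_array_equal(MIRROR_X @ MIRROR_X, np.eye(3))

    def test_empty_half_rejected(self):
        cloud = PointCloud([[1.0, 0, 0], [2.0, 1.0, 0]])
        with pytest.raises(DegeneratePoseError):
            orientation_correct(cloud)


class TestCurvatureScalars:
    def test_euler_formula(self):
        assert normal_curvature_euler(3, 1, 0.0) == pytest.approx(3)
        assert normal_curvature_euler(3, 1, np.pi / 2) == pytest.approx(1)
        assert normal_curvature_euler(3, 1, np.pi / 4) == pytest.approx(2)

    def test_mean_gaussian(self):
        assert mean_gaussian_curvature(4, 2) == pytest.approx((3, 8))
        assert mean_gaussian_curvature(1, -1) == pytest.approx((0, -1))
        # sphere of radius 0.5
        assert mean_gaussian_curvature(2, 2) == pytest.approx((2, 4))

    def test_order_violation_rejected(self):
        with pytest.raises(ParameterError):
            mean_gaussian_curvature(2, 4)
        with pytest.raises(ParameterError):
            normal_curvature_euler(1, 3, 0.0)


class TestSurfaceTaxonomy:
    @pytest.mark.parametrize("H,K,expected", [
        (-1, -2, SurfaceType.SADDLE_VALLEY),
        (-1, 0, SurfaceType.VALLEY),
        (-1, 2, SurfaceType.WELL),
        (0, 0, SurfaceType.PLANE),
        (0, -1, SurfaceType.MINIMAL_SADDLE),
        (1, -2, SurfaceType.SADDLE_RIDGE),
        (1, 0, SurfaceType.RIDGE),
        (1, 2, SurfaceType.PEAK),
    ])
    def test_eight_realizable_classes(self, H, K, expected):
        assert classify_surface_type(H, K, 0.1, 0.1) is expected

    def test_impossible_combination_rejected(self):
        with pytest.raises(ImpossibleSurfaceTypeError):
            classify_surface_type(0.0, 1.0, 0.1, 0.1)

    def test_epsilon_deadband(self):
        assert classify_surface_type(0.05, 0.0, 0.1, 0.1) is SurfaceType.PLANE

    def test_bad_eps_rejected(self):
        with pytest.raises(ParameterError):
            classify_surface_type(1, 1, 0.0, 0.1)
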