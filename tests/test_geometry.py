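"""Pinhole projection, triangulation and rigid registration."""

import numpy as np
import pytest

from gesturecap import (
    BehindCameraError,
    DegenerateFitError,
    DegenerateGeometryError,
    GeometryError,
    RigidTransform,
    load_camera_params,
    midpoint_triangulate,
    project,
    reprojection_rms,
    rigid_fit,
    save_camera_params,
    triangulate_batch,
    triangulate_pair,
    undistort_points,
)
from gesturecap.geometry import CameraParams, distort_normalized

from conftest import make_camera


class TestProjection:
    def test_point_on_optical_axis_hits_principal_point(self, simple_camera):
        np.testing.assert_allclose(
            project(np.array([0.0, 0.0, 1000.0]), simple_camera), [960.0, 540.0]
        )

    def test_lateral_offset_scales_by_focal_over_depth(self, simple_camera):
        np.testing.assert_allclose(
            project(np.array([100.0, 0.0, 1000.0]), simple_camera), [1060.0, 540.0]
        )

    def test_behind_camera_raises(self, simple_camera):
        with pytest.raises(BehindCameraError):
            project(np.array([0.0, 0.0, -5.0]), simple_camera)

    def test_matches_independent_distortion_formula(self):
        """Full-model projection equals a from-scratch evaluation of the
        radial-tangential polynomial."""
        rng = np.random.default_rng(42)
        dist = np.array([-0.2, 0.05, 0.001, -0.002, 0.01])
        cam = make_camera([100, 50, -2000], [0, 0, 500], fx=1100.0, dist=dist)
        pts = rng.normal(0, 300, (50, 3))
        pts[:, 2] += 500.0
        uv = project(pts, cam)
        k1, k2, p1, p2, k3 = dist
        for point, uv_got in zip(pts, uv):
            pc = cam.rotation @ point + cam.translation
            x, y = pc[0] / pc[2], pc[1] / pc[2]
            r2 = x * x + y * y
            rad = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
            xd = x * rad + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
            yd = y * rad + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
            expected = (cam.fx * xd + cam.cx, cam.fy * yd + cam.cy)
            np.testing.assert_allclose(uv_got, expected, rtol=1e-12)

    def test_undistort_inverts_distortion(self):
        rng = np.random.default_rng(7)
        dist = np.array([-0.1, 0.02, 0.0005, -0.001, 0.003])
        cam = make_camera([0, 0, -1000], [0, 0, 0], dist=dist)
        xy = rng.uniform(-0.3, 0.3, (200, 2))
        xd = distort_normalized(xy, dist)
        uv = np.stack([cam.fx * xd[:, 0] + cam.cx, cam.fy * xd[:, 1] + cam.cy], -1)
        np.testing.assert_allclose(undistort_points(uv, cam), xy, atol=1e-10)

    def test_invalid_camera_params_rejected(self):
        with pytest.raises(GeometryError):
            CameraParams("x", -1.0, 1.0, 0, 0, np.zeros(5), np.eye(3), np.zeros(3))
        with pytest.raises(GeometryError):
            CameraParams(
                "x", 1.0, 1.0, 0, 0, np.zeros(5),
                np.diag([1.0, 1.0, -1.0]), np.zeros(3),
            )

    def test_camera_file_round_trip(self, tmp_path):
        cam = make_camera([500, 0, -3000], [0, 0, 0],
                          dist=[-0.05, 0.01, 5e-4, -5e-4, 2e-3])
        path = tmp_path / "cam.json"
        save_camera_params(cam, path)
        back = load_camera_params(path)
        np.testing.assert_array_equal(back.rotation, cam.rotation)
        np.testing.assert_array_equal(back.translation, cam.translation)
        assert back.fx == cam.fx


class TestTriangulation:
    def _pair(self, dist=None):
        # two cameras with a 200 mm baseline looking down +z from z=-1000
        c1 = make_camera([-100, 0, -1000], [0, 0, 1000], dist=dist, camera_id="a")
        c2 = make_camera([100, 0, -1000], [0, 0, 1000], dist=dist, camera_id="b")
        return c1, c2

    def test_exact_round_trip_200mm_baseline(self):
        c1, c2 = self._pair()
        target = np.array([0.0, 0.0, 1000.0])
        pt, conf = triangulate_pair(
            (*project(target, c1), 0.8), (*project(target, c2), 0.9), c1, c2
        )
        np.testing.assert_allclose(pt, target, atol=1e-6)
        assert conf == 0.8

    def test_confidence_is_pairwise_minimum(self):
        c1, c2 = self._pair()
        target = np.array([50.0, -30.0, 800.0])
        _, conf = triangulate_pair(
            (*project(target, c1), 0.9), (*project(target, c2), 0.2), c1, c2
        )
        assert conf == pytest.approx(0.2)

    def test_round_trip_with_distortion_batch(self):
        dist = [-0.1, 0.02, 0.0005, -0.001, 0.003]
        c1, c2 = self._pair(dist=dist)
        rng = np.random.default_rng(3)
        pts = rng.normal(0, 200, (500, 3)) + [0, 0, 1000]
        uv1 = project(pts, c1)
        uv2 = project(pts, c2)
        rec, ok = triangulate_batch(uv1, uv2, c1, c2)
        assert ok.all()
        assert np.max(np.linalg.norm(rec - pts, axis=1)) < 1e-6

    def test_missing_observation_flagged_not_raised(self):
        c1, c2 = self._pair()
        uv1 = np.array([[960.0, 540.0], [np.nan, np.nan]])
        uv2 = np.array([[980.0, 540.0], [980.0, 540.0]])
        pts, ok = triangulate_batch(uv1, uv2, c1, c2)
        assert ok[0] and not ok[1]
        assert np.isnan(pts[1]).all()

    def test_coincident_centers_raise(self, simple_camera):
        with pytest.raises(DegenerateGeometryError):
            triangulate_pair(
                (960, 540, 1.0), (960, 540, 1.0), simple_camera, simple_camera
            )

    def test_midpoint_method_agrees_with_dlt(self):
        c1, c2 = self._pair()
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 150, (100, 3)) + [0, 0, 900]
        uv1, uv2 = project(pts, c1), project(pts, c2)
        dlt, ok = triangulate_batch(uv1, uv2, c1, c2)
        mid = midpoint_triangulate(uv1, uv2, c1, c2)
        assert ok.all()
        np.testing.assert_allclose(dlt, mid, atol=1e-6)

    def test_error_grows_monotonically_with_pixel_noise(self):
        """Mean reconstruction error is monotone over sigma in {0,1,2,4} px."""
        c1, c2 = self._pair()
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 200, (400, 3)) + [0, 0, 1500]
        uv1, uv2 = project(pts, c1), project(pts, c2)
        errs = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            n1 = uv1 + rng.normal(0, sigma, uv1.shape)
            n2 = uv2 + rng.normal(0, sigma, uv2.shape)
            rec, ok = triangulate_batch(n1, n2, c1, c2)
            errs.append(np.mean(np.linalg.norm(rec[ok] - pts[ok], axis=1)))
        assert errs == sorted(errs)
        assert errs[0] < 1e-6


class TestReprojectionRms:
    def test_zero_when_observations_equal_projections(self, simple_camera):
        pts = np.array([[0, 0, 1000.0], [100, 50, 2000.0]])
        obs = project(pts, simple_camera)
        assert reprojection_rms(pts, obs, simple_camera) == 0.0

    def test_three_four_five_residual(self, simple_camera):
        pts = np.array([[0, 0, 1000.0]])
        obs = np.array([[963.0, 544.0]])  # residual (3, 4) -> 5 px
        assert reprojection_rms(pts, obs, simple_camera) == pytest.approx(5.0)

    def test_matches_naive_loop_and_permutation_invariant(self, simple_camera):
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 200, (40, 3)) + [0, 0, 1500]
        obs = project(pts, simple_camera) + rng.normal(0, 2, (40, 2))
        got = reprojection_rms(pts, obs, simple_camera)
        total = 0.0
        for p, o in zip(pts, obs):
            pr = project(p, simple_camera)
            total += (pr[0] - o[0]) ** 2 + (pr[1] - o[1]) ** 2
        assert got == pytest.approx(np.sqrt(total / 40), rel=1e-12)
        perm = rng.permutation(40)
        assert reprojection_rms(pts[perm], obs[perm], simple_camera) == pytest.approx(
            got, rel=1e-12
        )

    def test_empty_input_errors(self, simple_camera):
        with pytest.raises(GeometryError):
            reprojection_rms(np.empty((0, 3)), np.empty((0, 2)), simple_camera)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestRigidFit:
    def test_identical_sets_give_identity(self):
        rng = np.random.default_rng(0)
        P = rng.normal(0, 100, (20, 3))
        fit = rigid_fit(P, P)
        np.testing.assert_allclose(fit.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.t, 0, atol=1e-10)

    def test_recovers_applied_transform_exactly(self):
        rng = np.random.default_rng(1)
        P = rng.normal(0, 100, (30, 3))
        R0 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t0 = np.array([10.0, 20.0, 30.0])
        Q = P @ R0.T + t0
        fit = rigid_fit(P, Q)
        np.testing.assert_allclose(fit.R, R0, atol=1e-9)
        np.testing.assert_allclose(fit.t, t0, atol=1e-9)

    def test_noisy_fit_beats_random_transforms(self):
        """Monte-Carlo oracle: the LS fit residual is below 2 sigma and
        below the residual of 1000 random rigid transforms."""
        rng = np.random.default_rng(2)
        sigma = 1.0
        P = rng.normal(0, 200, (100, 3))
        R0 = _random_rotation(rng)
        t0 = rng.normal(0, 100, 3)
        Q = P @ R0.T + t0 + rng.normal(0, sigma, (100, 3))
        fit = rigid_fit(P, Q)
        res = np.sqrt(np.mean(np.sum((fit.apply(P) - Q) ** 2, axis=1)))
        assert res < 2 * sigma * np.sqrt(3)
        for _ in range(1000):
            Rr = _random_rotation(rng)
            tr = t0 + rng.normal(0, 20, 3)
            rr = np.sqrt(np.mean(np.sum((P @ Rr.T + tr - Q) ** 2, axis=1)))
            assert res <= rr + 1e-12

    def test_collinear_points_rejected(self):
        P = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateFitError):
            rigid_fit(P, P + 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateFitError):
            rigid_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_near_planar_reflection_corrected(self):
        """det(R) stays +1 even when the best unconstrained map would be a
        reflection of a (near-)planar set."""
        rng = np.random.default_rng(3)
        P = rng.normal(0, 100, (50, 3))
        P[:, 2] *= 1e-9  # squash to a plane
        Q = P.copy()
        Q[:, 2] *= -1  # mirrored correspondences
        fit = rigid_fit(P, Q)
        assert np.linalg.det(fit.R) == pytest.approx(1.0, abs=1e-9)


class TestRigidTransform:
    def test_apply_then_inverse_is_identity(self):
        rng = np.random.default_rng(4)
        tf = RigidTransform(_random_rotation(rng), rng.normal(0, 50, 3), 1.3)
        pts = rng.normal(0, 100, (20, 3))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-9)

    def test_composition_matches_sequential_application(self):
        rng = np.random.default_rng(5)
        a = RigidTransform(_random_rotation(rng), rng.normal(0, 50, 3), 0.9)
        b = RigidTransform(_random_rotation(rng), rng.normal(0, 50, 3), 1.2)
        pts = rng.normal(0, 100, (15, 3))
        np.testing.assert_allclose(
            a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-9
        )

    def test_reflection_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
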