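"""PCA frame, Rodrigues rotation, circle fitting, and the metric transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ringcal import (
    ColoredPointCloud,
    MetricTransform,
    apply_transform,
    build_metric_transform,
    fit_circle,
    lsq_refine_circle,
    pca_frame,
    project_to_plane,
    ransac_circle,
    rodrigues,
    scale_factor,
)
from ringcal.errors import AmbiguousOrientationError, DegenerateGeometryError, FitFailedError, ParameterError

from conftest import annulus_points


class TestPcaFrame:
    def test_axis_aligned_plane(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (200, 2)), np.full(200, 5.0)])
        frame = pca_frame(pts)
        assert abs(frame.origin[2] - 5.0) < 1e-12
        assert abs(abs(frame.e3[2]) - 1.0) < 1e-9
        # orthonormal right-handed triplet
        B = np.column_stack([frame.e1, frame.e2, frame.e3])
        np.testing.assert_allclose(B.T @ B, np.eye(3), atol=1e-9)
        assert np.linalg.det(B) > 0

    def test_normal_equivariance_under_rotation(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (500, 2)), np.zeros(500)])
        R = Rotation.from_rotvec([0.7, -0.3, 0.2]).as_matrix()
        frame = pca_frame(pts @ R.T)
        expected = R @ np.array([0, 0, 1.0])
        assert min(np.linalg.norm(frame.e3 - expected), np.linalg.norm(frame.e3 + expected)) < 1e-6

    def test_three_points_exact_plane(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 1.0]])
        frame = pca_frame(pts)
        n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        n = n / np.linalg.norm(n)
        assert min(np.linalg.norm(frame.e3 - n), np.linalg.norm(frame.e3 + n)) < 1e-9

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(10.0), [1, 2, 3])
        with pytest.raises(DegenerateGeometryError):
            pca_frame(pts)


class TestRodrigues:
    def test_identity_for_parallel(self):
        np.testing.assert_allclose(rodrigues([0, 0, 1], [0, 0, 1]), np.eye(3), atol=1e-15)

    def test_quarter_turn_hand_computed(self):
        # k = (0,1,0), theta = pi/2: maps z onto x
        R = rodrigues([0, 0, 1], [1, 0, 0])
        np.testing.assert_allclose(R @ [0, 0, 1], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(R, [[0, 0, 1], [0, 1, 0], [-1, 0, 0]], atol=1e-12)

    def test_antiparallel_contract(self):
        R = rodrigues([0, 0, 1], [0, 0, -1])
        np.testing.assert_allclose(R @ [0, 0, 1], [0, 0, -1], atol=1e-12)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert abs(np.linalg.det(R) - 1) < 1e-12

    def test_invariants_on_random_pairs(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            a, b = rng.normal(size=(2, 3))
            a /= np.linalg.norm(a)
            b /= np.linalg.norm(b)
            R = rodrigues(a, b)
            worst = max(
                worst,
                np.abs(R @ a - b).max(),
                np.abs(R.T @ R - np.eye(3)).max(),
                abs(np.linalg.det(R) - 1),
            )
        assert worst < 1e-10

    def test_agrees_with_scipy_rotation(self):
        # independent route: axis-angle via scipy for random non-degenerate pairs
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.normal(size=(2, 3))
            a /= np.linalg.norm(a)
            b /= np.linalg.norm(b)
            axis = np.cross(a, b)
            if np.linalg.norm(axis) < 1e-6:
                continue
            theta = np.arccos(np.clip(a @ b, -1, 1))
            R_ref = Rotation.from_rotvec(theta * axis / np.linalg.norm(axis)).as_matrix()
            np.testing.assert_allclose(rodrigues(a, b), R_ref, atol=1e-12)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ParameterError):
            rodrigues([0, 0, 2], [1, 0, 0])


class TestProjectToPlane:
    def test_basis_semantics(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (100, 2)), np.zeros(100)])
        frame = pca_frame(pts)
        np.testing.assert_allclose(project_to_plane(frame.origin[None, :], frame), [[0, 0]], atol=1e-12)
        np.testing.assert_allclose(
            project_to_plane((frame.origin + 3 * frame.e1)[None, :], frame), [[3, 0]], atol=1e-12
        )

    def test_in_plane_isometry_on_circle(self, rng):
        t = np.linspace(0, 2 * np.pi, 300, endpoint=False)  # balanced: centroid = center
        circle = np.column_stack([7 * np.cos(t), 7 * np.sin(t), np.zeros(300)])
        R = Rotation.from_rotvec([0.4, 0.1, -0.8]).as_matrix()
        frame = pca_frame(circle @ R.T + [1, 2, 3])
        flat = project_to_plane(circle @ R.T + [1, 2, 3], frame)
        d = np.linalg.norm(flat - flat.mean(axis=0), axis=1)
        np.testing.assert_allclose(d, 7.0, atol=1e-9)


class TestRansacCircle:
    def test_exact_circle_recovered(self, rng):
        t = rng.uniform(0, 2 * np.pi, 100)
        pts = np.column_stack([2 + 5 * np.cos(t), -1 + 5 * np.sin(t)])
        fit = ransac_circle(pts, inlier_tol=1e-6, seed=1)
        assert np.abs(fit.center2d - [2, -1]).max() < 1e-6
        assert abs(fit.radius - 5) < 1e-6
        assert fit.inlier_mask.all()
        assert fit.d_fitted == 2 * fit.radius

    def test_three_point_circumcircle(self):
        fit = ransac_circle(np.array([[1.0, 0], [0, 1], [-1, 0]]), inlier_tol=1e-9, seed=0)
        np.testing.assert_allclose(fit.center2d, [0, 0], atol=1e-9)
        assert abs(fit.radius - 1) < 1e-9

    def test_robust_to_background_outliers(self):
        # 40% uniform clutter in the bounding box; 20 seeds must all succeed
        for seed in range(20):
            gen = np.random.default_rng(seed)
            t = gen.uniform(0, 2 * np.pi, 300)
            circle = np.column_stack([2 + 5 * np.cos(t), -1 + 5 * np.sin(t)])
            clutter = gen.uniform([-4, -7], [8, 5], (200, 2))
            pts = np.vstack([circle, clutter])
            fit = fit_circle(pts, inlier_tol=0.05 * 5, seed=seed)
            assert abs(fit.radius - 5) / 5 < 0.01
            assert fit.inlier_mask[:300].mean() >= 0.95

    def test_insufficient_inliers_fail(self, rng):
        pts = rng.uniform(0, 1, (100, 2))
        with pytest.raises(FitFailedError) as exc:
            ransac_circle(pts, inlier_tol=1e-4, min_inlier_frac=0.5, seed=0)
        assert exc.value.best_inlier_frac is not None

    def test_deterministic_given_seed(self, rng):
        pts = annulus_points(rng, 500, 10.0, 1.0)[:, :2]
        a = ransac_circle(pts, seed=4)
        b = ransac_circle(pts, seed=4)
        assert a.radius == b.radius and np.array_equal(a.inlier_mask, b.inlier_mask)


class TestLsqRefineCircle:
    def test_exact_inliers_are_fixed_point(self, rng):
        t = rng.uniform(0, 2 * np.pi, 200)
        pts = np.column_stack([3 * np.cos(t) + 1, 3 * np.sin(t) - 2])
        init = ransac_circle(pts, inlier_tol=1e-9, seed=0)
        fit = lsq_refine_circle(pts, init.inlier_mask, init)
        assert abs(fit.radius - 3) < 1e-10
        assert np.abs(fit.center2d - [1, -2]).max() < 1e-10
        assert fit.rms_residual < 1e-12

    def test_estimator_concentration_under_noise(self):
        # radius error within 3*sigma/sqrt(n) of truth across 20 seeds
        for seed in range(20):
            gen = np.random.default_rng(100 + seed)
            t = gen.uniform(0, 2 * np.pi, 500)
            r = 5 + gen.normal(0, 0.05, 500)
            pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
            fit = lsq_refine_circle(pts)
            assert abs(fit.radius - 5) < 3 * 0.05 / np.sqrt(500) * 1.5

    def test_half_arc_noiseless_exact(self, rng):
        # occlusion-robustness kernel: geometric LS is exact on partial arcs
        t = rng.uniform(0, np.pi, 300)
        pts = np.column_stack([4 * np.cos(t) + 2, 4 * np.sin(t) + 1])
        fit = lsq_refine_circle(pts)
        assert abs(fit.radius - 4) < 1e-9
        assert np.abs(fit.center2d - [2, 1]).max() < 1e-9

    def test_too_few_inliers_rejected(self):
        with pytest.raises(ParameterError):
            lsq_refine_circle(np.zeros((10, 2)), np.zeros(10, dtype=bool))


class TestScaleFactor:
    @pytest.mark.parametrize("d_fitted,d_true,expected", [(200, 200, 1.0), (100, 200, 2.0), (400, 200, 0.5)])
    def test_ratio(self, d_fitted, d_true, expected):
        assert scale_factor(d_fitted, d_true) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ParameterError):
            scale_factor(0, 200)


def _ring_and_plant(rng, normal_sign=1.0):
    ring = annulus_points(rng, 2000, 100.0, 5.0)
    plant = rng.uniform(-30, 30, (500, 3)) + [0, 0, normal_sign * 150]
    return ring, ColoredPointCloud(plant, np.tile([0.2, 0.8, 0.2], (500, 1)))


class TestMetricTransform:
    def test_known_similarity_recovered(self, rng):
        ring, plant = _ring_and_plant(rng)
        R_star = Rotation.from_rotvec([0.5, -0.4, 0.3]).as_matrix()
        s_star, t_star = 0.02, np.array([3.0, -2.0, 1.0])
        obs_ring = s_star * ring @ R_star.T + t_star
        obs_plant = ColoredPointCloud(
            s_star * plant.points @ R_star.T + t_star, plant.colors
        )
        frame = pca_frame(obs_ring)
        circle = fit_circle(project_to_plane(obs_ring, frame), seed=0)
        T = build_metric_transform(frame, circle, obs_plant, d_true=200.0)
        assert abs(T.s - 1 / s_star) / (1 / s_star) < 1e-3  # annulus width limits precision
        world_ring = T.s * obs_ring @ T.R + T.t
        assert np.abs(world_ring[:, 2]).max() < 1e-6  # ring plane at z=0
        # the true ring center (t_star in observed coords) maps near the origin
        world_center = T.s * (t_star @ T.R) + T.t
        assert np.abs(world_center).max() < 0.5

    def test_mirrored_scene_same_world_output(self, rng):
        # plant below the plane in reconstruction coords: sign correction flips
        ring, plant_above = _ring_and_plant(rng)
        plant_below = ColoredPointCloud(plant_above.points * [1, 1, -1], plant_above.colors)
        frame = pca_frame(ring)
        circle = fit_circle(project_to_plane(ring, frame), seed=0)
        T_up = build_metric_transform(frame, circle, plant_above, 200.0)
        T_dn = build_metric_transform(frame, circle, plant_below, 200.0)
        up_world = apply_transform(plant_above, T_up)
        dn_world = apply_transform(plant_below, T_dn)
        assert up_world.points[:, 2].mean() > 0
        assert dn_world.points[:, 2].mean() > 0

    def test_plant_on_plane_ambiguous(self, rng):
        ring, _ = _ring_and_plant(rng)
        flat = ColoredPointCloud(
            np.column_stack([np.zeros((50, 2)) + 1.0, np.zeros(50)]), np.full((50, 3), 0.5)
        )
        frame = pca_frame(ring)
        circle = fit_circle(project_to_plane(ring, frame), seed=0)
        with pytest.raises(AmbiguousOrientationError):
            build_metric_transform(frame, circle, flat, 200.0)

    def test_double_application_rejected(self, rng):
        _, plant = _ring_and_plant(rng)
        T = MetricTransform(np.eye(3), 1.0, np.zeros(3))
        metric = apply_transform(plant, T)
        with pytest.raises(ParameterError):
            apply_transform(metric, T)

    def test_identity_transform_changes_only_units(self, rng):
        _, plant = _ring_and_plant(rng)
        out = apply_transform(plant, MetricTransform(np.eye(3), 1.0, np.zeros(3)))
        np.testing.assert_array_equal(out.points, plant.points)
        assert out.units == "mm"

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    def test_similarity_scales_all_distances(self, seed, s):
        gen = np.random.default_rng(seed)
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        T = MetricTransform(R, s, gen.uniform(-10, 10, 3))
        pts = gen.uniform(-5, 5, (20, 3))
        cloud = ColoredPointCloud(pts, np.full((20, 3), 0.5))
        out = apply_transform(cloud, T)
        for i, j in [(0, 1), (5, 7), (10, 19)]:
            d_in = np.linalg.norm(pts[i] - pts[j])
            d_out = np.linalg.norm(out.points[i] - out.points[j])
            assert abs(d_out - s * d_in) <= 1e-9 * max(1.0, s * d_in)

    def test_json_round_trip_bit_exact(self, tmp_path, rng):
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        T = MetricTransform(R, np.pi, rng.normal(size=3), 200.0, 63.66, 1.23e-4)
        path = tmp_path / "t.json"
        T.to_json(path)
        back = MetricTransform.from_json(path)
        assert np.array_equal(back.R, T.R) and back.s == T.s and np.array_equal(back.t, T.t)
        assert back.d_fitted == T.d_fitted and back.rms_residual == T.rms_residual

    def test_missing_fields_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"R": [[1,0,0],[0,1,0],[0,0,1]], "s": 1.0}')
        with pytest.raises(ParameterError):
            MetricTransform.from_json(path)
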