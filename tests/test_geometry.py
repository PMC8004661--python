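"""Silhouette moments, spheroid fitting, elevation, pose and lifting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinfit.geometry import (
    DegenerateCovarianceError,
    DegenerateShapeError,
    GeometryError,
    ModelType,
    SpheroidShape,
    TooFewPixelsError,
    ViewPose,
    _pose_rows,
    assign_elevation_signs,
    elevation_angle_magnitude,
    fit_ellipse,
    fit_spheroid,
    lift_points,
    lift_to_3d,
    pose_matrix,
    quadric_matrix,
)
from spinfit.synthetic import rasterize_ellipse


from tests.helpers import make_observation as _obs


class TestFitEllipse:
    def test_disc_moments_match_radius(self):
        # uniform disc: coordinate variance r^2/4 along any axis
        mask = rasterize_ellipse(50, 50, 0.0, 100, 100, (200, 200))
        e = fit_ellipse(mask, stride=1)
        assert e.cx == pytest.approx(100, abs=0.5)
        assert e.cy == pytest.approx(100, abs=0.5)
        assert e.a == pytest.approx(50, rel=0.02)
        assert e.b == pytest.approx(50, rel=0.02)

    @pytest.mark.parametrize("a,b,phi", [(80, 50, 30.0), (120, 40, 120.0), (90, 45, 100.0)])
    def test_rotated_ellipse_recovery(self, a, b, phi):
        mask = rasterize_ellipse(a, b, phi, a + 10, a + 10, (2 * a + 20, 2 * a + 20))
        e = fit_ellipse(mask, stride=1)
        assert e.a == pytest.approx(a, rel=0.02)
        assert e.b == pytest.approx(b, rel=0.02)
        d = abs((e.orientation_deg - phi + 90.0) % 180.0 - 90.0)
        assert d < 1.0
        # eigenvectors are unit and orthogonal with the fixed sign convention
        assert np.linalg.norm(e.v1) == pytest.approx(1.0, abs=1e-12)
        assert abs(e.v1 @ e.v2) < 1e-12
        assert e.v1[0] >= 0.0

    def test_stride_has_negligible_effect_at_fruit_scale(self):
        mask = rasterize_ellipse(80, 50, 30.0, 90, 90, (180, 180))
        e1 = fit_ellipse(mask, stride=1)
        e4 = fit_ellipse(mask, stride=4)
        assert abs(e4.a - e1.a) / e1.a < 0.01
        assert abs(e4.b - e1.b) / e1.b < 0.01

    def test_too_few_pixels_raises(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(TooFewPixelsError):
            fit_ellipse(mask, stride=1)
        # enough pixels at stride 1 but not after striding
        mask[5, 6] = mask[5, 7] = True
        with pytest.raises(TooFewPixelsError):
            fit_ellipse(mask, stride=8)

    def test_collinear_pixels_degenerate(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 2:18] = True  # a single row has zero variance across rows
        with pytest.raises(DegenerateCovarianceError):
            fit_ellipse(mask, stride=1)

    def test_scaled_observation(self):
        mask = rasterize_ellipse(80, 50, 30.0, 90, 90, (180, 180))
        e = fit_ellipse(mask, stride=1)
        s = e.scaled(0.25)
        assert s.a == pytest.approx(e.a / 4)
        assert s.cx == pytest.approx(e.cx / 4)
        assert s.lambda1 == pytest.approx(e.lambda1 / 16)


class TestFitSpheroid:
    def test_sphere_mean_of_axes(self):
        shape = fit_spheroid([_obs(60, 60)] * 3, "sphere")
        assert shape.A == shape.B == pytest.approx(60)

    def test_oblate_mean_major_min_minor(self):
        views = [_obs(100, 90), _obs(100, 70), _obs(102, 60), _obs(98, 85)]
        shape = fit_spheroid(views, "oblate")
        assert shape.A == pytest.approx(100.0)
        assert shape.B == pytest.approx(60.0)

    def test_prolate_max_major_mean_minor(self):
        views = [_obs(100, 60), _obs(80, 62), _obs(90, 58)]
        shape = fit_spheroid(views, "prolate")
        assert shape.A == pytest.approx(100.0)
        assert shape.B == pytest.approx(60.0)

    def test_empty_observations_error(self):
        with pytest.raises(GeometryError):
            fit_spheroid([], "sphere")

    def test_effectively_spherical_warns_not_raises(self):
        with pytest.warns(UserWarning, match="effectively spherical"):
            shape = fit_spheroid([_obs(80, 80 - 1e-9)], "oblate")
        assert shape.A == pytest.approx(80.0)


class TestElevationAngle:
    shape = SpheroidShape(ModelType.OBLATE, 100.0, 60.0)

    def test_edge_on_and_face_on(self):
        assert elevation_angle_magnitude(60.0, self.shape) == pytest.approx(np.pi / 2)
        assert elevation_angle_magnitude(100.0, self.shape) == pytest.approx(0.0)

    def test_intermediate_value(self):
        # b = 80: cos(theta) = sqrt((6400 - 3600) / (10000 - 3600))
        expected = np.arccos(np.sqrt(0.4375))
        assert elevation_angle_magnitude(80.0, self.shape) == pytest.approx(expected, abs=1e-12)

    def test_noise_outside_range_is_clamped(self):
        assert elevation_angle_magnitude(101.0, self.shape) == pytest.approx(0.0)
        assert elevation_angle_magnitude(59.0, self.shape) == pytest.approx(np.pi / 2)

    def test_sphere_and_degenerate_shape_raise(self):
        with pytest.raises(DegenerateShapeError):
            elevation_angle_magnitude(50.0, SpheroidShape(ModelType.SPHERE, 80, 80))
        with pytest.raises(DegenerateShapeError):
            elevation_angle_magnitude(50.0, SpheroidShape(ModelType.OBLATE, 80, 80))


class TestElevationSigns:
    def test_increasing_downwards_all_positive(self):
        b = [60, 70, 80, 90]
        m = [0.9, 0.6, 0.4, 0.2]
        out = assign_elevation_signs(b, m, "down")
        assert np.all(out > 0)
        np.testing.assert_allclose(out, m)

    def test_increasing_upwards_all_negative(self):
        out = assign_elevation_signs([60, 70, 80], [0.9, 0.6, 0.4], "up")
        assert np.all(out < 0)

    def test_decreasing_downwards_all_negative(self):
        out = assign_elevation_signs([90, 80, 70], [0.2, 0.5, 0.8], "down")
        assert np.all(out < 0)

    def test_extremum_takes_smoother_branch(self):
        # minimum of b at the centre; signed neighbours are -0.5 and +0.48,
        # so the centre picks the candidate closest to their mean: -0.05
        b = [7.0, 5.0, 3.0, 5.0, 7.0]
        m = [0.9, 0.5, 0.05, 0.48, 0.9]
        out = assign_elevation_signs(b, m, "down")
        assert out[1] == pytest.approx(-0.5)
        assert out[3] == pytest.approx(0.48)
        assert out[2] == pytest.approx(-0.05)

    def test_flat_sequence_defaults(self):
        out = assign_elevation_signs([50.0, 50.0], [0.3, 0.3], "down")
        assert out.shape == (2,)


class TestPoseMatrix:
    def test_zero_elevation_oblate_rows(self):
        P = pose_matrix(_obs(100, 60), 0.0, "oblate").P
        np.testing.assert_allclose(P, [[0, 0, 1], [1, 0, 0], [0, 1, 0]], atol=1e-15)

    def test_edge_on_oblate_first_row(self):
        P = pose_matrix(_obs(100, 60), np.pi / 2, "oblate").P
        np.testing.assert_allclose(P[0], [0, 1, 0], atol=1e-12)

    def test_sphere_identity_pose(self):
        pose = pose_matrix(_obs(80, 80), 0.7, "sphere")
        assert pose.theta == 0.0
        np.testing.assert_allclose(pose.P, np.eye(3))

    @given(
        theta=st.floats(-np.pi / 2, np.pi / 2),
        psi=st.floats(0.0, np.pi - 1e-6),
        model=st.sampled_from([ModelType.OBLATE, ModelType.PROLATE]),
    )
    def test_pose_orthonormal_det_one(self, theta, psi, model):
        v1 = np.array([np.cos(psi), np.sin(psi)])
        obs = _obs(100, 60, v1=v1)
        P = pose_matrix(obs, theta, model).P
        np.testing.assert_allclose(P @ P.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(P) == pytest.approx(1.0, abs=1e-9)


class TestLifting:
    def test_sphere_centre_and_limb(self):
        shape = SpheroidShape(ModelType.SPHERE, 50.0, 50.0)
        pose = ViewPose(0.0, np.eye(3), (100.0, 100.0))
        assert lift_to_3d(100, 100, shape, pose).z == pytest.approx(50.0)
        assert lift_to_3d(150, 100, shape, pose).z == pytest.approx(0.0)
        assert lift_to_3d(151, 100, shape, pose) is None

    def test_oblate_face_on_centre_height_is_B(self):
        shape = SpheroidShape(ModelType.OBLATE, 100.0, 60.0)
        pose = ViewPose(0.0, _pose_rows(np.array([1.0, 0]), np.array([0, 1.0]), 0.0,
                                        ModelType.OBLATE), (0.0, 0.0))
        pt = lift_to_3d(0.0, 0.0, shape, pose)
        assert pt.z == pytest.approx(60.0, abs=1e-9)
        amat = quadric_matrix(shape, pose)
        p = pt.as_array()
        assert abs(p @ amat @ p - 1.0) < 1e-9

    def test_lifted_points_satisfy_quadric(self):
        rng = np.random.default_rng(5)
        shape = SpheroidShape(ModelType.PROLATE, 90.0, 55.0)
        theta = 0.6
        pose = ViewPose(theta, _pose_rows(np.array([0.0, 1.0]), np.array([-1.0, 0.0]),
                                          theta, ModelType.PROLATE), (0.0, 0.0))
        amat = quadric_matrix(shape, pose)
        xy = rng.uniform(-40, 40, size=(200, 2))
        pts, valid = lift_points(xy, shape, pose)
        assert valid.any()
        for p in pts[valid]:
            assert abs(p @ amat @ p - 1.0) < 1e-6

    def test_closed_form_matches_brute_force_scan(self):
        from spinfit.benchmarks import lifting_cross_check

        out = lifting_cross_check(seed=7, n_instances=30)
        assert out["scan_diff_px_max"] < 1e-3
        assert out["quadric_residual_max"] < 1e-6


class TestRoundTripProjection:
    def test_rendered_oblate_elevation_recovered(self):
        """Rendering at a known elevation and inverting the axis relation
        recovers the angle (forward-model consistency)."""
        from spinfit.synthetic import SyntheticConfig, render_sequence

        A, B, theta = 120.0, 70.0, 35.0
        cfg = SyntheticConfig(model_type="oblate", A=A, B=B, image_size=(280, 280),
                              n_views=1, initial_elevation_deg=theta, seed=3)
        seq = render_sequence(cfg)
        obs = fit_ellipse(seq.masks[0], stride=1)
        est = np.degrees(
            elevation_angle_magnitude(obs.b, SpheroidShape(ModelType.OBLATE, A, B))
        )
        assert est == pytest.approx(theta, abs=2.0)
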