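"""Pinhole/distortion model, rectification and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesselcam import (CameraIntrinsics, RigGeometry, PhantomSpec,
                       pixel_scale_from_square, project, rectify_image,
                       render_square_sequence, segment_frame, undistort_points)
from vesselcam.optics import (ConvergenceError, DegenerateConfigurationError,
                              ProjectionError, ScaleError, calibrate,
                              distort_normalized)
from scipy.spatial.transform import Rotation


INTR = CameraIntrinsics(fx=600, fy=590, cx=320, cy=240,
                        k1=-0.2, k2=0.05, k3=0.0, p1=0.001, p2=-0.0005,
                        width=640, height=480)


class TestProject:
    def test_optical_axis_maps_to_principal_point(self):
        px = project(np.array([0.0, 0.0, 1.7]), INTR)
        np.testing.assert_allclose(px, [INTR.cx, INTR.cy], atol=1e-12)

    def test_pure_pinhole_is_linear(self):
        intr = CameraIntrinsics(fx=500, fy=500, cx=319.5, cy=239.5,
                                width=640, height=480)
        w = 0.25
        px = project(np.array([w * 2.0, 0.0, 2.0]), intr)
        assert px[0] == pytest.approx(intr.fx * w + intr.cx, abs=1e-12)

    def test_barrel_term_pulls_points_inward(self):
        intr = CameraIntrinsics(fx=500, fy=500, cx=319.5, cy=239.5, k1=-0.1,
                                width=640, height=480)
        # normalized radius 0.5 along x: displacement factor (1 - 0.1 * 0.25)
        px = project(np.array([0.5, 0.0, 1.0]), intr)
        assert px[0] - intr.cx == pytest.approx(500 * 0.5 * (1 - 0.1 * 0.25), abs=1e-12)

    def test_non_positive_depth_raises(self):
        with pytest.raises(ProjectionError):
            project(np.array([0.1, 0.1, 0.0]), INTR)


class TestUndistort:
    def test_zero_distortion_is_identity(self):
        intr = CameraIntrinsics(fx=500, fy=500, cx=319.5, cy=239.5,
                                width=640, height=480)
        pts = np.array([[10.0, 20.0], [300.0, 400.0], [639.0, 0.0]])
        np.testing.assert_allclose(undistort_points(pts, intr), pts, atol=1e-12)

    def test_principal_point_is_fixed_point(self):
        p = np.array([INTR.cx, INTR.cy])
        np.testing.assert_allclose(undistort_points(p, INTR), p, atol=1e-12)

    @pytest.mark.parametrize("k1", [-0.3, -0.1, 0.1, 0.3])
    def test_round_trip_on_grid(self, k1):
        intr = CameraIntrinsics(fx=600, fy=600, cx=319.5, cy=239.5, k1=k1,
                                p1=0.0005, p2=-0.0005, width=640, height=480)
        xs, ys = np.meshgrid(np.linspace(60, 580, 10), np.linspace(60, 420, 10))
        grid = np.column_stack([xs.ravel(), ys.ravel()])
        # distort the pinhole positions, then invert
        norm = np.column_stack([(grid[:, 0] - intr.cx) / intr.fx,
                                (grid[:, 1] - intr.cy) / intr.fy])
        distorted = distort_normalized(norm, intr)
        pixels = np.column_stack([intr.fx * distorted[:, 0] + intr.cx,
                                  intr.fy * distorted[:, 1] + intr.cy])
        recovered = undistort_points(pixels, intr)
        assert np.abs(recovered - grid).max() < 1e-6

    def test_non_convergence_reports_residual(self):
        intr = CameraIntrinsics(fx=600, fy=600, cx=319.5, cy=239.5, k1=-0.9,
                                width=640, height=480)
        with pytest.raises(ConvergenceError) as err:
            undistort_points(np.array([[630.0, 470.0]]), intr, max_iter=2)
        assert err.value.residual > 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(x=st.floats(-0.4, 0.4), y=st.floats(-0.3, 0.3),
           k1=st.floats(-0.25, 0.25))
    def test_round_trip_property(self, x, y, k1):
        intr = CameraIntrinsics(fx=600, fy=600, cx=319.5, cy=239.5, k1=k1,
                                width=640, height=480)
        pix = np.array([intr.fx * x + intr.cx, intr.fy * y + intr.cy])
        d = distort_normalized(np.array([[x, y]]), intr)[0]
        pix_d = np.array([intr.fx * d[0] + intr.cx, intr.fy * d[1] + intr.cy])
        np.testing.assert_allclose(undistort_points(pix_d, intr), pix, atol=1e-5)


class TestRectify:
    def test_zero_distortion_returns_image_unchanged(self, rng):
        intr = CameraIntrinsics(fx=300, fy=300, cx=119.5, cy=89.5,
                                width=240, height=180)
        img = rng.integers(0, 256, size=(180, 240), dtype=np.uint8)
        assert np.array_equal(rectify_image(img, intr), img)

    @pytest.fixture
    def barrel_setup(self):
        rig = RigGeometry(image_size=(480, 270), object_distance=0.30)
        distorted = CameraIntrinsics(fx=420, fy=420, cx=239.5, cy=134.5,
                                     k1=-0.25, width=480, height=270)
        straight = rig.default_intrinsics()
        return rig, distorted, straight

    @staticmethod
    def _left_edge_line_residual(image):
        """RMS residual of a line fitted to the sub-pixel left edge."""
        mask = image > 100
        rows = np.nonzero(mask.any(axis=1))[0]
        band = rows[10:-10]  # interior rows, away from the corners
        mid = (200 + 30) / 2.0
        left = []
        for r in band:
            c = int(np.nonzero(image[r].astype(float) >= mid)[0][0])
            lo, hi = float(image[r, c - 1]), float(image[r, c])
            frac = (mid - lo) / (hi - lo) if hi > lo else 0.0
            left.append(c - 1 + frac)
        left = np.asarray(left)
        fit = np.polyval(np.polyfit(band, left, 1), band)
        return float(np.sqrt(np.mean((left - fit) ** 2)))

    def test_rectified_square_edges_are_straight(self, barrel_setup):
        rig, distorted, straight = barrel_setup
        seq, _ = render_square_sequence(0.05, 0.10, rig, seed=0,
                                        intrinsics=distorted)
        rectified = rectify_image(seq.frames[1], distorted)
        # straight to within half a pixel (residual dominated by the
        # deliberately aliased rendering, not by remaining curvature)
        assert self._left_edge_line_residual(rectified) <= 0.5

    def test_rectified_area_matches_undistorted_render(self, barrel_setup):
        rig, distorted, straight = barrel_setup
        seq_d, _ = render_square_sequence(0.05, 0.10, rig, seed=0,
                                          intrinsics=distorted)
        seq_u, _ = render_square_sequence(0.05, 0.10, rig, seed=0,
                                          intrinsics=straight)
        for i in range(2):
            area_rect = segment_frame(rectify_image(seq_d.frames[i], distorted)).area_px
            area_true = segment_frame(seq_u.frames[i]).area_px
            # fx differs between the two cameras; compare at equal focal length
            assert area_rect == pytest.approx(area_true, rel=0.01)


def _synthesize_views(intr, noise_sd=0.0, n_views=7, seed=0):
    # target spans most of the field of view so distortion is observable
    gx, gy = np.meshgrid(np.arange(12), np.arange(9))
    obj = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * 0.05
    obj -= obj.mean(axis=0)
    obj3 = np.column_stack([obj, np.zeros(len(obj))])
    rots = [(0.0, 0.0, 0.0), (0.25, 0.1, 0.05), (-0.2, 0.25, -0.1),
            (0.1, -0.3, 0.2), (-0.3, -0.15, -0.05), (0.35, 0.2, -0.15),
            (-0.1, 0.35, 0.1)][:n_views]
    rng = np.random.default_rng(seed)
    views = []
    for rv in rots:
        pts = Rotation.from_rotvec(rv).apply(obj3) + np.array([0.01, -0.02, 0.75])
        px = project(pts, intr)
        if noise_sd:
            px = px + rng.normal(0, noise_sd, px.shape)
        views.append(px)
    return obj, views


class TestCalibrate:
    def test_noise_free_views_recover_parameters(self):
        obj, views = _synthesize_views(INTR)
        res = calibrate(obj, views, image_size=(640, 480))
        est = res.intrinsics
        for name in ["fx", "fy", "cx", "cy"]:
            assert getattr(est, name) == pytest.approx(getattr(INTR, name), rel=1e-3)
        for name in ["k1", "k2", "p1", "p2"]:
            assert getattr(est, name) == pytest.approx(getattr(INTR, name), abs=2e-4)
        assert res.rms_px < 1e-3

    def test_zero_distortion_views_yield_null_coefficients(self):
        intr = CameraIntrinsics(fx=550, fy=560, cx=310, cy=250,
                                width=640, height=480)
        obj, views = _synthesize_views(intr)
        res = calibrate(obj, views, image_size=(640, 480))
        assert np.all(np.abs(res.intrinsics.distortion) < 1e-3)

    def test_noisy_views_reach_noise_level_rms(self):
        obj, views = _synthesize_views(INTR, noise_sd=0.2, seed=3)
        res = calibrate(obj, views, image_size=(640, 480))
        assert 0.1 < res.rms_px < 0.35
        assert res.intrinsics.k1 == pytest.approx(INTR.k1, rel=0.05)

    def test_repeated_pose_views_are_degenerate(self):
        obj, views = _synthesize_views(INTR, n_views=1)
        with pytest.raises((DegenerateConfigurationError, ValueError)):
            calibrate(obj, [views[0]] * 3, image_size=(640, 480))


class TestPixelScale:
    def test_closed_form(self):
        assert pixel_scale_from_square(10000, 0.05).mm_per_pixel == pytest.approx(0.5)
        assert pixel_scale_from_square(40000, 0.10).mm_per_pixel == pytest.approx(0.5)

    def test_double_distance_doubles_scale(self):
        near = pixel_scale_from_square(10000, 0.05)
        far = pixel_scale_from_square(10000 / 4, 0.05)
        assert far.mm_per_pixel == pytest.approx(2 * near.mm_per_pixel)

    def test_non_positive_area_raises(self):
        with pytest.raises(ScaleError):
            pixel_scale_from_square(0, 0.05)
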