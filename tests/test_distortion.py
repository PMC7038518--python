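"""Radial distortion model: forward map, calibration, correction."""

import numpy as np
import pytest

from rhizopan.distortion import (DistortionError, DistortionProfile,
                                 calibrate, calibrate_grid, correct,
                                 forward_distort, forward_distort_points,
                                 identity_profile, make_dot_grid,
                                 undistort_points)

PROFILE = DistortionProfile(cx=60.0, cy=50.0, k=(0.05, 0.02, -0.01),
                            r_norm=78.0)


def _grid_points(n_side=10, lo=10, hi=110):
    xs = np.linspace(lo, hi, n_side)
    ys = np.linspace(lo, hi - 20, n_side)
    return np.array([(x, y) for y in ys for x in xs])


class TestForwardMap:
    def test_zero_coefficients_are_identity(self):
        prof = identity_profile((100, 120))
        pts = _grid_points()
        assert np.array_equal(forward_distort_points(pts, prof), pts)
        img = np.random.default_rng(0).random((100, 120)).astype(np.float32)
        assert np.allclose(forward_distort(img, prof), img, atol=1e-6)

    def test_center_is_fixed_point(self):
        pts = np.array([[PROFILE.cx, PROFILE.cy]])
        out = forward_distort_points(pts, PROFILE)
        assert np.allclose(out, pts)

    def test_unit_normalized_radius_displacement(self):
        # at rho = 1 with k = (0.1, 0, 0) the radius grows by exactly 10%
        prof = DistortionProfile(cx=0, cy=0, k=(0.1, 0.0, 0.0), r_norm=50.0)
        out = forward_distort_points(np.array([[50.0, 0.0]]), prof)
        assert out[0, 0] == pytest.approx(55.0)

    def test_monotonicity_guard_rejects_folding_profile(self):
        bad = DistortionProfile(cx=60, cy=50, k=(-0.9, 0.0, 0.0), r_norm=60.0)
        with pytest.raises(DistortionError):
            bad.check_monotone(80.0)
        img = np.zeros((100, 120))
        with pytest.raises(DistortionError):
            correct(img, bad)


class TestCalibrate:
    def test_exact_recovery_from_noiseless_points(self):
        pts = _grid_points()
        distorted = forward_distort_points(pts, PROFILE)
        fit = calibrate(pts, distorted, r_norm=PROFILE.r_norm,
                        center0=(PROFILE.cx, PROFILE.cy))
        assert np.allclose(fit.k, PROFILE.k, atol=1e-6)
        assert np.allclose([fit.cx, fit.cy], [PROFILE.cx, PROFILE.cy],
                           atol=1e-6)
        assert fit.rms_px < 1e-8

    def test_noisy_recovery_within_five_percent(self):
        # calibration shot at full sensor resolution: 100 dots, 0.2 px
        # centroid noise; the leading coefficient and the radial mapping
        # itself must come back (the higher-order pair is nearly collinear
        # over the frame and is checked through the mapping)
        rng = np.random.default_rng(11)
        xs = np.linspace(40, 600, 10)
        ys = np.linspace(40, 440, 10)
        pts = np.array([(x, y) for y in ys for x in xs])
        true = DistortionProfile(cx=320.0, cy=240.0, k=(0.15, 0.05, -0.02),
                                 r_norm=344.0)
        observed = forward_distort_points(pts, true) \
            + rng.normal(0, 0.2, (100, 2))
        fit = calibrate(pts, observed, r_norm=true.r_norm,
                        center0=(true.cx, true.cy))
        assert abs(fit.k[0] - true.k[0]) / abs(true.k[0]) <= 0.05
        gap = np.abs(forward_distort_points(pts, fit)
                     - forward_distort_points(pts, true)).max()
        assert gap <= 0.25

    def test_collinear_points_rejected(self):
        pts = np.array([(float(x), 50.0) for x in range(12)])
        with pytest.raises(DistortionError):
            calibrate(pts, pts)

    def test_single_radius_rejected(self):
        ang = np.linspace(0, 2 * np.pi, 13)[:-1]
        pts = np.stack([60 + 40 * np.cos(ang), 50 + 40 * np.sin(ang)], axis=1)
        with pytest.raises(DistortionError):
            calibrate(pts, pts, center0=(60, 50))

    def test_too_few_points_rejected(self):
        pts = _grid_points(3)[:8]
        with pytest.raises(DistortionError):
            calibrate(pts, pts)

    def test_grid_image_calibration(self):
        grid, centers = make_dot_grid((101, 120), spacing=18, dot_radius=1.6,
                                      margin=10)
        prof_true = DistortionProfile(cx=59.5, cy=50.0, k=(0.06, 0.01, 0.0),
                                      r_norm=78.0)
        fit = calibrate_grid(forward_distort(grid, prof_true), centers)
        # mappings agree even if the parameterization differs slightly
        pts = _grid_points(8, 15, 105)
        d_true = forward_distort_points(pts, prof_true)
        d_fit = forward_distort_points(pts, fit)
        assert np.abs(d_true - d_fit).max() < 0.3


class TestCorrect:
    def test_point_round_trip_sub_millipixel(self):
        pts = _grid_points()
        back = undistort_points(forward_distort_points(pts, PROFILE), PROFILE)
        assert np.abs(back - pts).max() <= 1e-3

    def test_image_round_trip(self, scene75):
        img = scene75.texture[:101, :120]
        prof = DistortionProfile(cx=59.5, cy=50.0, k=(0.05, 0.01, 0.0),
                                 r_norm=78.0)
        rt = correct(forward_distort(img, prof), prof)
        # valid interior: exclude the border band lost to out-of-frame fill
        inner = (slice(8, -8), slice(8, -8))
        err = np.abs(rt[inner] - img[inner]).mean()
        assert err <= 2 / 255

    def test_identity_profile_correct_is_noop(self):
        img = np.random.default_rng(1).random((80, 90)).astype(np.float32)
        out = correct(img, identity_profile(img.shape))
        assert np.allclose(out, img, atol=1e-6)

    def test_grid_lines_straight_after_correction(self):
        # bright horizontal lines, bowed by the lens, must come back straight
        h, w = 101, 120
        img = np.zeros((h, w))
        rows = [20, 35, 50, 65, 80]
        for r in rows:
            img[r - 1:r + 2] = 1.0
        prof = DistortionProfile(cx=59.5, cy=50.0, k=(0.06, 0.01, 0.0),
                                 r_norm=78.0)
        fixed = correct(forward_distort(img, prof), prof)
        for r in rows:
            band = fixed[r - 4:r + 5, 10:110]
            weights = band.sum(axis=0)
            cols = weights > 0.5 * weights.max()
            centroid = ((np.arange(r - 4, r + 5)[:, None] * band).sum(axis=0)
                        / np.maximum(band.sum(axis=0), 1e-9))
            dev = np.abs(centroid[cols] - r)
            assert dev.max() <= 0.5
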