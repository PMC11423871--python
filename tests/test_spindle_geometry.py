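"""Tactoid construction, boundary extraction and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from spindlenematic.exceptions import InvalidGeometryError, LowContrastError
from spindlenematic.spindle_geometry import (BoundaryCurve,
                                             PoleIndentedTactoid,
                                             extract_boundary, fit_tactoid,
                                             pool_tactoids,
                                             tactoid_boundary_radius,
                                             tactoid_cross_section,
                                             tactoid_junction)
from spindlenematic.synthetic_data import make_tactoid_boundary

from conftest import L0, R_BELT, R_CAP


class TestConstruction:
    def test_junction_on_both_circles(self):
        xj, yj = tactoid_junction(L0, R_BELT, R_CAP)
        c = (R_BELT**2 - L0**2) / (2 * R_BELT)
        assert np.hypot(xj, yj - c) == pytest.approx(np.hypot(L0, c), rel=1e-12)
        assert np.hypot(xj - L0, yj) == pytest.approx(R_CAP, rel=1e-12)

    def test_curve_through_apex_and_tip(self):
        curve = make_tactoid_boundary(L0, R_BELT, R_CAP, 360)
        assert np.min(np.hypot(curve[:, 0], curve[:, 1] - R_BELT)) < 1e-9
        assert np.min(np.hypot(curve[:, 0] - (L0 - R_CAP), curve[:, 1])) < 1e-9

    def test_mirror_symmetries(self):
        curve = make_tactoid_boundary(L0, R_BELT, R_CAP, 240)
        pts = {(round(x, 9), round(y, 9)) for x, y in curve}
        assert all((round(-x, 9), round(-y, 9)) in pts for x, y in curve)
        assert all((round(x, 9), round(-y, 9)) in pts for x, y in curve)

    def test_cap_limit_degenerates_to_pure_tactoid(self):
        phi = np.linspace(-np.pi, np.pi, 720)
        prev = None
        for r_cap in (0.5, 0.1, 0.01):
            b = tactoid_boundary_radius(phi, L0, R_BELT, r_cap)
            tip = tactoid_boundary_radius(0.0, L0, R_BELT, r_cap)
            assert tip == pytest.approx(L0 - r_cap)
            prev = b
        # at tiny r_cap the tip approaches the virtual pole (cusp limit)
        assert tip == pytest.approx(L0, abs=0.011)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(InvalidGeometryError):
            tactoid_junction(10.0, 8.0, 11.0)   # r_cap >= l0
        with pytest.raises(InvalidGeometryError):
            make_tactoid_boundary(10.0, 8.0, 0.0, 64)

    def test_n_points_minimum(self):
        with pytest.raises(ValueError):
            make_tactoid_boundary(L0, R_BELT, R_CAP, 8)

    def test_cross_section_annular_near_pole(self):
        outer, inner = tactoid_cross_section(np.array([0.0, 12.0, 14.0]),
                                             L0, R_BELT, R_CAP)
        assert outer[0] == pytest.approx(R_BELT)
        assert inner[0] == 0.0
        assert inner[1] > 0.0            # inside the polar bite


class TestExtractBoundary:
    def test_indicator_image_boundary_within_one_pixel(self):
        from spindlenematic.spindle_geometry import tactoid_cap_angle
        px = 0.2
        n = 180
        ss = 4  # supersampled (area-weighted) indicator rendering
        xs = (np.arange(n * ss) + 0.5 - n * ss / 2) * (px / ss)
        xx, yy = np.meshgrid(xs, xs)
        phi = np.arctan2(yy, xx)
        fine = (np.hypot(xx, yy) <=
                tactoid_boundary_radius(phi, 12.0, 7.0, 3.0)).astype(float)
        img = fine.reshape(n, ss, n, ss).mean(axis=(1, 3))
        bc = extract_boundary(img, px, blur_um=0.4)
        truth = tactoid_boundary_radius(bc.phi, 12.0, 7.0, 3.0)
        err = np.abs(bc.radius - truth)
        # at the four cap/belt junction corners the gradient maximum is
        # ambiguous within the smoothing scale; everywhere else the
        # boundary must localize to a pixel
        phi_j = tactoid_cap_angle(12.0, 7.0, 3.0)
        fold = np.minimum(np.abs(np.abs(bc.phi) - phi_j),
                          np.abs(np.pi - np.abs(bc.phi) - phi_j))
        away = fold > np.deg2rad(4)
        assert np.max(err[away]) < px
        assert np.max(err) < 2 * px

    def test_blank_image_low_contrast(self):
        with pytest.raises(LowContrastError):
            extract_boundary(np.zeros((64, 64)), 0.25)

    def test_mirror_symmetric_input_gives_symmetric_boundary(self,
                                                             clean_movie):
        bc = extract_boundary(clean_movie.retardance.mean(axis=0),
                              clean_movie.pixel_size)
        # compare b(phi) with b(-phi) via interpolation
        order = np.argsort(bc.phi)
        phi, rad = bc.phi[order], bc.radius[order]
        mirrored = np.interp(-phi, phi, rad, period=2 * np.pi)
        assert np.median(np.abs(rad - mirrored)) < clean_movie.pixel_size


def _ellipse_rms(phi, b):
    def cost(p):
        a, bb = np.abs(p) + 1e-6
        r = a * bb / np.hypot(bb * np.cos(phi), a * np.sin(phi))
        return np.mean((r - b) ** 2)
    res = minimize(cost, [b.max(), b.min()], method="Nelder-Mead")
    return np.sqrt(res.fun)


def _rectangle_rms(phi, b):
    def cost(p):
        w, h = np.abs(p) + 1e-6
        r = np.minimum(w / np.maximum(np.abs(np.cos(phi)), 1e-9),
                       h / np.maximum(np.abs(np.sin(phi)), 1e-9))
        return np.mean((r - b) ** 2)
    res = minimize(cost, [b.max(), b.min()], method="Nelder-Mead")
    return np.sqrt(res.fun)


class TestFitTactoid:
    def test_noiseless_round_trip(self):
        phi = np.linspace(-np.pi, np.pi, 400, endpoint=False) + 0.003
        b = tactoid_boundary_radius(phi, L0, R_BELT, R_CAP)
        fit = fit_tactoid(BoundaryCurve(phi, b))
        assert fit.l0 == pytest.approx(L0, rel=0.005)
        assert fit.r_belt == pytest.approx(R_BELT, rel=0.005)
        assert fit.r_cap == pytest.approx(R_CAP, rel=0.005)
        assert not fit.degenerate

    @pytest.mark.parametrize("ratio_cap,ratio_belt", [
        (0.15, 0.3), (0.3, 0.5), (0.5, 0.7), (0.7, 0.85), (0.26, 0.53),
    ])
    def test_round_trip_parameter_sweep(self, ratio_cap, ratio_belt):
        l0 = 12.0
        phi = np.linspace(-np.pi, np.pi, 360, endpoint=False) + 0.002
        b = tactoid_boundary_radius(phi, l0, ratio_belt * l0, ratio_cap * l0)
        fit = fit_tactoid(BoundaryCurve(phi, b))
        assert fit.l0 == pytest.approx(l0, rel=0.01)
        assert fit.r_cap == pytest.approx(ratio_cap * l0, rel=0.02)
        assert fit.r_belt == pytest.approx(ratio_belt * l0, rel=0.01)

    def test_recovery_under_radial_noise(self):
        rng = np.random.default_rng(7)
        phi = np.linspace(-np.pi, np.pi, 400, endpoint=False)
        b = tactoid_boundary_radius(phi, L0, R_BELT, R_CAP)
        b_noisy = b * (1 + 0.01 * rng.standard_normal(b.shape))
        fit = fit_tactoid(BoundaryCurve(phi, b_noisy))
        assert fit.l0 == pytest.approx(L0, rel=0.05)
        assert fit.r_belt == pytest.approx(R_BELT, rel=0.05)
        assert fit.r_cap == pytest.approx(R_CAP, rel=0.05)

    def test_circle_flags_degenerate(self):
        phi = np.linspace(-np.pi, np.pi, 300, endpoint=False)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_tactoid(BoundaryCurve(phi, np.full_like(phi, 7.0)))
        assert fit.degenerate

    def test_scale_invariance_via_upsampled_image(self, clean_movie):
        bc1 = extract_boundary(clean_movie.retardance.mean(axis=0),
                               clean_movie.pixel_size)
        from scipy import ndimage
        up = ndimage.zoom(clean_movie.retardance.mean(axis=0), 2, order=1)
        bc2 = extract_boundary(up, clean_movie.pixel_size / 2)
        f1, f2 = fit_tactoid(bc1), fit_tactoid(bc2)
        assert f2.l0 == pytest.approx(f1.l0, rel=0.005)

    def test_beats_ellipse_and_rectangle_baselines(self):
        rng = np.random.default_rng(11)
        phi = np.linspace(-np.pi, np.pi, 360, endpoint=False)
        b = tactoid_boundary_radius(phi, L0, R_BELT, R_CAP)
        b = b * (1 + 0.005 * rng.standard_normal(b.shape))
        fit = fit_tactoid(BoundaryCurve(phi, b))
        assert fit.rms < _ellipse_rms(phi, b)
        assert fit.rms < _rectangle_rms(phi, b)


class TestPooling:
    def test_identical_fits_zero_se(self):
        f = PoleIndentedTactoid(10.0, 5.0, 2.0)
        pooled = pool_tactoids([f] * 5)
        assert pooled.r_belt_se == 0.0 and pooled.r_cap_se == 0.0

    def test_two_fit_mean(self):
        fits = [PoleIndentedTactoid(10.0, 5.0, 2.0),
                PoleIndentedTactoid(10.0, 6.0, 2.0)]
        pooled = pool_tactoids(fits)
        assert pooled.r_belt_ratio == pytest.approx(0.55)

    def test_single_fit_passthrough(self):
        pooled = pool_tactoids([PoleIndentedTactoid(10.0, 5.0, 2.0)])
        assert pooled.r_belt_ratio == pytest.approx(0.5)
        assert np.isnan(pooled.r_belt_se)

    def test_se_matches_analytic_at_n16(self):
        rng = np.random.default_rng(5)
        sigma = 0.05
        ses = []
        for _ in range(200):
            fits = [PoleIndentedTactoid(1.0, 0.5 + sigma * rng.standard_normal(),
                                        0.25) for _ in range(16)]
            ses.append(pool_tactoids(fits).r_belt_se)
        assert np.mean(ses) == pytest.approx(sigma / np.sqrt(16), rel=0.2)
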