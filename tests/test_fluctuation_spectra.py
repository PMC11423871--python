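"""Fluctuation extraction, spectra, peak detection, density coupling."""

import numpy as np
import pytest

import spindlenematic.synthetic_data as sd
from spindlenematic.director_model import theta_arcs
from spindlenematic.fluctuation_spectra import (FluctuationStack,
                                                compute_fluctuations,
                                                density_fluctuation_coupling,
                                                find_peak, local_binarize,
                                                slice_qy, spectrum)
from spindlenematic.movie_registration import PolScopeMovie

from conftest import L0


def _stack(field):
    return FluctuationStack(field, 0.25, 3.6, field.shape[1] * 0.25)


def _striped_mask(n=48, spacing=2.4, width=0.8, x_extent=5.0, px=0.25):
    y = (np.arange(n) + 0.5 - n / 2) * px
    x = (np.arange(n) + 0.5 - n / 2) * px
    yy, xx = np.meshgrid(y, x, indexing="ij")
    # stripe centers at multiples of the spacing: pattern symmetric about
    # the box edges so mirror padding preserves the periodicity
    stripes = np.abs(np.mod(yy + spacing / 2, spacing) - spacing / 2) \
        < width / 2
    return stripes & (np.abs(xx) < x_extent)


class TestComputeFluctuations:
    def _model_movie(self, offset=0.0, n=6):
        truth = sd.SpindleGroundTruth(n_frames=n, noise_sd=0.0,
                                      fluct=sd.FluctParams(amplitude=0.0))
        mv = sd.render_polscope_movie(truth)
        mv.slow_axis = mv.slow_axis + offset
        return mv

    def test_exact_model_gives_zero(self):
        st = compute_fluctuations(self._model_movie(), L0)
        assert np.max(np.abs(st.dny)) < 1e-9

    def test_uniform_offset_propagates(self):
        st = compute_fluctuations(self._model_movie(offset=0.1), L0)
        assert np.allclose(st.dny, 0.1, atol=1e-9)

    def test_amplitude_recovery(self):
        truth = sd.SpindleGroundTruth(
            n_frames=40, noise_sd=0.0,
            fluct=sd.FluctParams(amplitude=0.05, correlation_time=3.6),
            seed=8)
        mv = sd.render_polscope_movie(truth)
        st = compute_fluctuations(mv, L0)
        assert np.sqrt(np.mean(st.dny**2)) == pytest.approx(0.05, rel=0.1)

    def test_large_mean_angle_warns(self):
        mv = self._model_movie(offset=0.5)
        with pytest.warns(UserWarning, match="15 deg"):
            compute_fluctuations(mv, L0)


class TestSpectrum:
    def test_parseval(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 0.05, (24, 32, 32))
        sp = spectrum(_stack(f), lambda_im=1e-9)  # keep every mode
        dq = sp.qx[1] - sp.qx[0]
        total = np.nansum(sp.s_nn) * (dq / (2 * np.pi)) ** 2
        assert total == pytest.approx(f.var(), rel=0.05)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(1)
        acc = None
        for _ in range(6):
            f = rng.normal(0, 0.05, (64, 32, 32))
            qy, s = slice_qy(spectrum(_stack(f)), 8.0)
            acc = s if acc is None else acc + s
        assert acc[-3:].mean() / acc[:3].mean() == pytest.approx(1.0,
                                                                 abs=0.1)

    def test_synthetic_slope_minus_two(self):
        fl = sd.FluctParams(amplitude=0.05, correlation_time=10.0)
        acc = None
        for seed in range(4):
            f = sd.sample_fluctuation_field(fl, (32, 32), 0.25, 64, 3.6,
                                            seed=seed)
            qy, s = slice_qy(spectrum(_stack(f)), 8.0)
            acc = s if acc is None else acc + s
        # away from the q0 shoulder the slice decays as qy^-2
        sel = (qy > 2.0) & (qy < 12.0)
        slope = np.polyfit(np.log(qy[sel]), np.log(acc[sel]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.2)

    def test_padding_width_invariance(self):
        fl = sd.FluctParams(amplitude=0.05, correlation_time=10.0)
        f = sd.sample_fluctuation_field(fl, (32, 32), 0.25, 32, 3.6, seed=2)
        q1, s1 = slice_qy(spectrum(_stack(f), pad_factor=1), 8.0)
        q3, s3 = slice_qy(spectrum(_stack(f), pad_factor=3), 8.0)
        common = np.intersect1d(np.round(q1, 9), np.round(q3, 9))
        v1 = s1[np.isin(np.round(q1, 9), common)]
        v3 = s3[np.isin(np.round(q3, 9), common)]
        assert np.allclose(v1, v3, rtol=0.02)

    def test_cutoff_removes_only_the_ring(self):
        rng = np.random.default_rng(3)
        f = rng.normal(0, 0.05, (16, 32, 32))
        sp_all = spectrum(_stack(f), lambda_im=1e-9)
        sp_cut = spectrum(_stack(f), lambda_im=0.8)
        dq = sp_all.qx[1] - sp_all.qx[0]
        removed = np.nansum(np.where(np.isnan(sp_cut.s_nn), sp_all.s_nn,
                                     0.0)) * (dq / (2 * np.pi)) ** 2
        kept = np.nansum(sp_cut.s_nn) * (dq / (2 * np.pi)) ** 2
        assert kept + removed == pytest.approx(f.var(), rel=0.05)

    def test_tiny_box_rejected(self):
        with pytest.raises(ValueError):
            spectrum(FluctuationStack(np.zeros((4, 1, 1)), 0.25, 1.0, 0.25))


class TestPeak:
    def test_clean_inverse_square_slice_has_no_peak(self):
        q0 = 2 * np.pi / 8.0
        qy = q0 * np.arange(1, 16)
        assert find_peak(qy, 1.0 / (q0**2 + qy**2)) is None

    def test_void_peak_at_lattice_frequency(self):
        # invariant: detected peak positions distribute within one mode
        # of 2*pi/spacing
        mask = _striped_mask()
        hits = []
        for seed in range(15):
            f = sd.sample_fluctuation_field(
                sd.FluctParams(amplitude=0.05, void_boost=3.0,
                               correlation_time=10.0),
                (48, 48), 0.25, 64, 3.6, seed=seed, void_mask=mask)
            qy, s = slice_qy(spectrum(_stack(f)), 12.0)
            pk = find_peak(qy, s)
            if pk:
                hits.append(pk[0])
        assert len(hits) >= 10
        bin_width = 2 * np.pi / 12.0
        assert abs(np.mean(hits) - 2 * np.pi / 2.4) < bin_width

    def test_peak_wavelength_arithmetic(self):
        mask = _striped_mask()
        f = sd.sample_fluctuation_field(
            sd.FluctParams(amplitude=0.05, void_boost=3.0,
                           correlation_time=10.0),
            (48, 48), 0.25, 128, 3.6, seed=0, void_mask=mask)
        qy, s = slice_qy(spectrum(_stack(f)), 12.0)
        qstar, lam = find_peak(qy, s)
        assert lam == pytest.approx(2 * np.pi / qstar, rel=1e-12)
        assert qstar == pytest.approx(2 * np.pi / 2.4, abs=0.4)


class TestLocalBinarize:
    def test_constant_image_all_ones(self):
        assert local_binarize(np.full((20, 20), 3.0), 0.25).all()

    def test_step_image_matches_step_away_from_edge(self):
        # disk radius comparable to the image so every local mean sees
        # both sides (with a strictly two-valued image, pixels whose
        # disk sees only their own side trivially equal the local mean)
        img = np.ones((30, 30))
        img[:, 15:] = 2.0
        m = local_binarize(img, 0.1, radius_um=2.0)  # radius 20 px
        step = np.zeros_like(img, dtype=bool)
        step[:, 15:] = True
        interior = np.zeros_like(step)
        interior[:, :12] = True
        interior[:, 18:] = True
        assert np.array_equal(m.astype(bool)[interior], step[interior])

    def test_radius_larger_than_image_is_global_threshold(self):
        rng = np.random.default_rng(4)
        img = rng.random((10, 10))
        m = local_binarize(img, 1.0, radius_um=100.0)
        assert np.array_equal(m.astype(bool), img >= img.mean())

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError):
            local_binarize(np.ones((5, 5)), 1.0, radius_um=0.5)


class TestDensityCoupling:
    def _field_level(self, boost, seed=0):
        """Construct stack + retardance whose low regions are exactly the
        boosted mask, isolating the coupling statistics."""
        mask = _striped_mask(x_extent=6.1)
        fl = sd.FluctParams(amplitude=0.05, void_boost=boost,
                            void_edge_um=0.0)
        f = sd.sample_fluctuation_field(fl, (48, 48), 0.25, 300, 3.6,
                                        seed=seed, void_mask=mask)
        ret = 6.0 - 1.5 * mask.astype(float)
        bin_mask = local_binarize(ret, 0.25, radius_um=2.0)
        return density_fluctuation_coupling(ret, np.abs(f).mean(axis=0),
                                            bin_mask)

    def test_ratio_recovery_at_paper_boost(self):
        ratios = [self._field_level(1.07, seed=s)[1] for s in range(6)]
        assert np.mean(ratios) == pytest.approx(1.07, abs=0.03)

    def test_no_coupling_baseline(self):
        slopes, ratios = zip(*[self._field_level(1.0, seed=s)
                               for s in range(6)])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)
        assert abs(np.mean(slopes)) < 0.005

    def test_ratio_monotone_in_boost(self):
        means = [np.mean([self._field_level(b, seed=s)[1]
                          for s in range(4)]) for b in (1.0, 1.07, 1.2)]
        assert means[0] < means[1] < means[2]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            density_fluctuation_coupling(np.ones(10), np.ones(10),
                                         np.ones(10))

    def test_movie_level_coupling_sign(self):
        # end-to-end: sparse voids, boosted fluctuations -> negative
        # slope of fluctuation vs retardance and ratio above one
        voids = sd.default_voids(n_chr=6, beta=11.0, waist=1.4,
                                 plate_radius=4.5, seed=1)
        ratios = []
        for seed in range(3):
            truth = sd.SpindleGroundTruth(
                n_frames=100, noise_sd=0.1, voids=voids, seed=seed,
                fluct=sd.FluctParams(amplitude=0.05, void_boost=1.3,
                                     correlation_time=10.0))
            mv = sd.render_polscope_movie(truth)
            st = compute_fluctuations(mv, L0)
            x, y = mv.frame_coords()
            sel = np.ix_(np.abs(y) <= 4.0, np.abs(x) <= 4.0)
            mr = mv.retardance.mean(axis=0)[sel]
            m = local_binarize(mr, mv.pixel_size, radius_um=2.0)
            _, r = density_fluctuation_coupling(mr,
                                                np.abs(st.dny).mean(axis=0),
                                                m)
            ratios.append(r)
        assert np.mean(ratios) > 1.01
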