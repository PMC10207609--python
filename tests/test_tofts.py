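import itertools

import numpy as np
import pytest

from dcequant import AIFCurve, DynamicSeries, LabelMask, fit_map, fit_pixel, tofts_forward
from dcequant.tofts import exp_conv


def closed_form_ct(ktrans, ve, vp, D, m, times):
    """Analytic extended Tofts solution for Cp = D exp(-m t)."""
    kep = (ktrans / ve) / 60.0
    kt = ktrans / 60.0
    return vp * D * np.exp(-m * times) + kt * D * (
        np.exp(-m * times) - np.exp(-kep * times)
    ) / (kep - m)


class TestForward:
    def test_null_parameters_give_zero(self, aif_short):
        ct = tofts_forward(0.0, 0.0, 0.0, aif_short)
        np.testing.assert_array_equal(ct, 0.0)

    def test_pure_plasma_term(self, aif_short):
        ct = tofts_forward(0.0, 0.0, 0.1, aif_short)
        np.testing.assert_allclose(ct, 0.1 * aif_short.cp, rtol=1e-12)

    @pytest.mark.parametrize("ktrans,ve", [(0.05, 0.5), (0.2, 0.3), (0.7, 0.2), (1.0, 0.35)])
    def test_matches_closed_form_for_mono_exponential_input(self, mono_exp_aif, ktrans, ve):
        aif, D, m = mono_exp_aif
        ct = tofts_forward(ktrans, ve, 0.05, aif)
        expected = closed_form_ct(ktrans, ve, 0.05, D, m, aif.times)
        assert np.max(np.abs(ct - expected)) < 1e-4

    def test_zero_before_bolus(self, aif_short):
        ct = tofts_forward(0.3, 0.3, 0.05, aif_short)
        pre = aif_short.times < 60.0
        np.testing.assert_array_equal(ct[pre], 0.0)

    def test_ve_zero_with_ktrans_positive_rejected(self, aif_short):
        with pytest.raises(ValueError, match="kep"):
            tofts_forward(0.2, 0.0, 0.05, aif_short)

    def test_exp_conv_exact_for_ramp_on_nonuniform_grid(self):
        # the recursion integrates piecewise-linear inputs exactly, so a
        # ramp must match the analytic integral even on an irregular grid
        rng = np.random.default_rng(6)
        t = np.concatenate([[0.0], np.cumsum(rng.uniform(0.5, 4.0, 80))])
        alpha, kep = 0.03, 0.012
        cp = alpha * t
        E = np.exp(-kep * t)
        # analytic: int_0^t alpha*tau e^{-kep(t-tau)} dtau
        expected = alpha * (t / kep - (1 - E) / kep**2)
        np.testing.assert_allclose(exp_conv(t, cp, kep), expected, atol=1e-10)


class TestFitPixel:
    def test_recovers_exact_parameters_noiseless(self, aif_full):
        ct = tofts_forward(0.20, 0.30, 0.05, aif_full)
        fit = fit_pixel(ct, aif_full)
        assert fit.converged
        assert fit.ktrans == pytest.approx(0.20, rel=0.01)
        assert fit.ve == pytest.approx(0.30, rel=0.01)
        assert fit.vp == pytest.approx(0.05, rel=0.01)
        assert fit.kep == pytest.approx(fit.ktrans / fit.ve)

    def test_grid_search_oracle_confirms_global_minimum(self, aif_short):
        """Exhaustive coarse grid search lands within one cell of the NLS fit."""
        ct = tofts_forward(0.20, 0.30, 0.05, aif_short)
        fit = fit_pixel(ct, aif_short)
        kt_grid = np.arange(0.01, 0.601, 0.01)
        ve_grid = np.arange(0.05, 0.601, 0.05)
        vp_grid = np.arange(0.0, 0.101, 0.01)
        best = (np.inf, None)
        for kt, ve in itertools.product(kt_grid, ve_grid):
            base = tofts_forward(kt, ve, 0.0, aif_short)
            for vp in vp_grid:
                rss = float(np.sum((base + vp * aif_short.cp - ct) ** 2))
                if rss < best[0]:
                    best = (rss, (kt, ve, vp))
        kt_b, ve_b, vp_b = best[1]
        assert abs(kt_b - fit.ktrans) <= 0.01 + 1e-9
        assert abs(ve_b - fit.ve) <= 0.05 + 1e-9
        assert abs(vp_b - fit.vp) <= 0.01 + 1e-9

    def test_flat_zero_curve_flags_ve_unidentifiable(self, aif_short):
        fit = fit_pixel(np.zeros(aif_short.times.size), aif_short)
        assert fit.converged
        assert fit.ktrans == 0.0 and fit.vp == 0.0
        assert not fit.ve_identifiable

    def test_noisy_median_ktrans_error_small(self, aif_short):
        ct = tofts_forward(0.25, 0.35, 0.04, aif_short)
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(40):
            fit = fit_pixel(ct + rng.normal(0.0, 0.02, ct.shape), aif_short)
            errs.append(abs(fit.ktrans - 0.25) / 0.25)
        assert np.median(errs) < 0.10

    def test_nested_two_parameter_model_has_higher_rss(self, aif_short):
        rng = np.random.default_rng(3)
        ct = tofts_forward(0.2, 0.3, 0.08, aif_short) + rng.normal(0, 0.01, aif_short.times.size)
        full = fit_pixel(ct, aif_short)
        nested = fit_pixel(ct, aif_short, fit_vp=False)
        assert nested.vp == pytest.approx(0.0, abs=1e-9)
        assert nested.rss >= full.rss - 1e-12

    def test_joint_linearity_in_aif_and_tissue_scale(self, aif_short):
        ct = tofts_forward(0.2, 0.3, 0.05, aif_short)
        scaled = AIFCurve(times=aif_short.times, cp=3.0 * aif_short.cp)
        fit = fit_pixel(3.0 * ct, scaled)
        assert fit.ktrans == pytest.approx(0.2, rel=1e-3)
        assert fit.ve == pytest.approx(0.3, rel=1e-3)
        assert fit.vp == pytest.approx(0.05, rel=1e-3)

    def test_short_washout_window_lowers_convergence_flag(self):
        # observation stops well within one reflux time constant 1/kep
        from dcequant import AcquisitionParams, AIFParams, evaluate_aif

        params = AcquisitionParams(n_frames=45, frame_interval=2.0, injection_start=20.0)
        aif = evaluate_aif(AIFParams(t0=20.0), params.frame_times, 0.45)
        ct = tofts_forward(0.05, 0.6, 0.02, aif)  # kep ~ 0.083/min, 1/kep ~ 12 min
        fit = fit_pixel(ct, aif)
        assert not fit.converged

    def test_too_few_post_injection_frames_rejected(self):
        from dcequant import AIFCurve

        times = np.arange(0.0, 20.0, 2.0)
        aif = AIFCurve(times=times, cp=np.r_[np.zeros(5), np.ones(5)])
        with pytest.raises(ValueError, match="post-injection"):
            fit_pixel(np.zeros(10), aif)


class TestFitMap:
    def test_matches_per_pixel_fits_and_order_invariance(self, aif_short, params_short):
        rng = np.random.default_rng(5)
        shape = (3, 3)
        data = np.empty(shape + (aif_short.times.size,))
        for r in range(3):
            for c in range(3):
                kt = 0.1 + 0.05 * (3 * r + c) / 8
                data[r, c] = tofts_forward(kt, 0.3, 0.04, aif_short) + rng.normal(
                    0, 0.005, aif_short.times.size
                )
        series = DynamicSeries(data=data, times=aif_short.times, unit="concentration_mM")
        mask = LabelMask(np.ones(shape, dtype=np.int32), {1: "all"})
        maps = fit_map(series, aif_short, mask)
        maps2 = fit_map(series, aif_short, mask)
        np.testing.assert_array_equal(maps["Ktrans"].masked(), maps2["Ktrans"].masked())
        for r in range(3):
            for c in range(3):
                ref = fit_pixel(data[r, c], aif_short)
                assert maps["Ktrans"].values[r, c] == pytest.approx(ref.ktrans)
                assert maps["kep"].values[r, c] == pytest.approx(ref.kep)

    def test_empty_mask_rejected(self, aif_short):
        series = DynamicSeries(
            data=np.zeros((2, 2, aif_short.times.size)),
            times=aif_short.times,
            unit="concentration_mM",
        )
        mask = LabelMask(np.zeros((2, 2), dtype=np.int32), {})
        with pytest.raises(ValueError, match="empty mask"):
            fit_map(series, aif_short, mask)
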