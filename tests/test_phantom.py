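import numpy as np
import pytest

from dcequant import (
    AcquisitionParams,
    RegionParams,
    ScalarMap,
    ScenarioSpec,
    make_truth,
    place_rim_rois,
    simulate_cohort,
    simulate_dce,
    simulate_vtr,
)
from dcequant.phantom import DEFAULT_REGION_PARAMS, add_rician_noise, rician_mean


class TestMakeTruth:
    def test_deterministic_given_seed(self):
        a = make_truth(grid_shape=(32, 32), seed=7)
        b = make_truth(grid_shape=(32, 32), seed=7)
        np.testing.assert_array_equal(a.masks.labels, b.masks.labels)
        assert a.regions == b.regions

    def test_regions_partition_grid(self, truth32):
        labels = truth32.masks.labels
        assert set(np.unique(labels)) == {0, 1, 2, 3}

    def test_rim_is_annulus_around_core(self, truth32):
        labels = truth32.masks.labels
        h, w = labels.shape
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
        assert r[labels == 3].max() < r[labels == 2].min() + 1.5  # core inside rim

    def test_invalid_region_params_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            make_truth(region_params={"tumor_rim": {"t1_pre": 1800, "m0": 1000,
                                                    "ktrans": 0.25, "ve": 0.9, "vp": 0.2}})


class TestSimulateVTR:
    def test_saturation_recovery_closed_form(self):
        truth = make_truth(grid_shape=(16, 16), region_params={
            "tumor_rim": RegionParams(t1_pre=1500.0, m0=1000.0, ktrans=0.25, ve=0.35, vp=0.04)
        })
        params = AcquisitionParams()
        vtr = simulate_vtr(truth, params, phase="pre")
        rim = truth.masks.labels == 2
        k = list(params.vtr_ladder).index(7500.0)
        expected = 1000.0 * (1.0 - np.exp(-5.0))  # ~993.26
        assert vtr.data[rim, k] == pytest.approx(expected, rel=1e-9)
        assert vtr.data.shape[2] == 8

    def test_post_with_zero_contrast_equals_pre(self, truth32):
        params = AcquisitionParams()
        zero = ScalarMap(np.zeros((32, 32)), "concentration_mM",
                         np.ones((32, 32), dtype=bool))
        pre = simulate_vtr(truth32, params, phase="pre", noise_sd=5.0, seed=3)
        post = simulate_vtr(truth32, params, phase="post", concentration=zero,
                            noise_sd=5.0, seed=3)
        np.testing.assert_array_equal(pre.data, post.data)

    def test_residual_contrast_shortens_recovery(self, truth32):
        params = AcquisitionParams()
        c = ScalarMap(np.full((32, 32), 0.5), "concentration_mM",
                      np.ones((32, 32), dtype=bool))
        pre = simulate_vtr(truth32, params, phase="pre")
        post = simulate_vtr(truth32, params, phase="post", concentration=c)
        rim = truth32.masks.labels == 2
        # shorter T1 recovers faster at short TR
        k_short = int(np.argmin(params.vtr_ladder))
        assert post.data[rim, k_short].mean() > pre.data[rim, k_short].mean()

    def test_negative_noise_sd_rejected(self, truth32):
        with pytest.raises(ValueError):
            simulate_vtr(truth32, AcquisitionParams(), noise_sd=-1.0)

    def test_post_requires_concentration_map(self, truth32):
        with pytest.raises(ValueError, match="concentration"):
            simulate_vtr(truth32, AcquisitionParams(), phase="post")


class TestSimulateDCE:
    def test_zero_parameters_give_flat_zero_concentration(self, params_short, aif_short):
        null = RegionParams(t1_pre=1800.0, m0=1000.0, ktrans=0.0, ve=0.0, vp=0.0)
        truth = make_truth(grid_shape=(24, 24), region_params={
            "tumor_rim": null, "tumor_core": null,
            "muscle": RegionParams(t1_pre=1200.0, m0=900.0, ktrans=0.0, ve=0.0, vp=0.0),
        })
        _, conc = simulate_dce(truth, aif_short, params_short)
        np.testing.assert_array_equal(conc.data, 0.0)

    def test_seeded_reproducibility_bit_identical(self, truth32, params_short, aif_short):
        s1, c1 = simulate_dce(truth32, aif_short, params_short, snr=20.0, seed=9)
        s2, c2 = simulate_dce(truth32, aif_short, params_short, snr=20.0, seed=9)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(c1.data, c2.data)

    def test_truth_concentration_nonnegative_and_zero_preinjection(
        self, truth32, params_short, aif_short
    ):
        _, conc = simulate_dce(truth32, aif_short, params_short, snr=20.0, seed=1)
        assert conc.data.min() >= 0.0
        pre = conc.times < 60.0
        np.testing.assert_array_equal(conc.data[:, :, pre], 0.0)

    def test_invalid_snr_rejected(self, truth32, params_short, aif_short):
        with pytest.raises(ValueError):
            simulate_dce(truth32, aif_short, params_short, snr=0.0)


class TestRicianNoise:
    def test_seeded_reproducibility(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        x = np.full((100,), 50.0)
        np.testing.assert_array_equal(
            add_rician_noise(x, 5.0, rng1), add_rician_noise(x, 5.0, rng2)
        )

    @pytest.mark.parametrize("snr", [10.0, 30.0])
    def test_sample_mean_matches_analytic_rician_mean(self, snr):
        """At SNR >= 10 the noisy mean sits at the Rician mean within 1%."""
        rng = np.random.default_rng(17)
        nu = 100.0
        sd = nu / snr
        noisy = add_rician_noise(np.full(200_000, nu), sd, rng)
        assert noisy.mean() == pytest.approx(float(rician_mean(nu, sd)), rel=0.01)
        # and the Rician mean itself exceeds nu (positive magnitude bias)
        assert rician_mean(nu, sd) > nu

    def test_rician_mean_zero_signal_limit(self):
        # pure-noise limit: E[R] = sd sqrt(pi/2)
        assert float(rician_mean(0.0, 2.0)) == pytest.approx(2.0 * np.sqrt(np.pi / 2), rel=1e-9)


class TestCohort:
    def _spec(self, **kw):
        base = dict(name="s", n_per_group=3,
                    group_effects={"control": {}, "treated": {"ktrans": 1.5}},
                    noise_snr=30.0, seed=4, biological_cv=0.0)
        base.update(kw)
        return ScenarioSpec(**base)

    def test_animal_count(self, truth32, params_short, aif_short):
        datasets, table = simulate_cohort(self._spec(n_per_group=8), truth32,
                                          params_short, aif_short)
        assert len(datasets) == 16
        assert len(table) == 16

    def test_multiplier_applied_exactly_without_biology(self, truth32, params_short, aif_short):
        _, table = simulate_cohort(self._spec(), truth32, params_short, aif_short)
        kt_control = table.loc[table.group == "control", "ktrans_true"].unique()
        kt_treated = table.loc[table.group == "treated", "ktrans_true"].unique()
        assert kt_control.size == 1 and kt_treated.size == 1
        assert kt_treated[0] == pytest.approx(1.5 * kt_control[0], rel=1e-12)
        assert kt_control[0] == pytest.approx(DEFAULT_REGION_PARAMS["tumor_rim"].ktrans)

    def test_null_scenario_identical_truth_distribution(self, truth32, params_short, aif_short):
        spec = self._spec(group_effects={"a": {}, "b": {}})
        _, table = simulate_cohort(spec, truth32, params_short, aif_short)
        assert table.groupby("group")["ktrans_true"].mean().nunique() == 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            self._spec(n_per_group=1)
        with pytest.raises(ValueError):
            self._spec(noise_snr=0.0)
        with pytest.raises(ValueError):
            self._spec(group_effects={"a": {}, "b": {"ktrans": -2.0}})


class TestRimROIs:
    def test_three_disjoint_rois_inside_rim(self, truth32):
        rois = place_rim_rois(truth32)
        labels = set(np.unique(rois.labels)) - {0}
        assert labels == {1, 2, 3}
        rim = truth32.masks.labels == 2
        assert np.all(rim[rois.labels > 0])


class TestMonotoneResponse:
    def test_higher_rim_ktrans_never_decreases_rim_auc(self, params_short, aif_short):
        from dcequant import metric_maps

        aucs = []
        for kt in (0.1, 0.25, 0.5):
            truth = make_truth(grid_shape=(24, 24), region_params={
                "tumor_rim": RegionParams(t1_pre=1800.0, m0=1000.0, ktrans=kt, ve=0.35, vp=0.04)
            })
            signal, _ = simulate_dce(truth, aif_short, params_short)  # noiseless
            maps = metric_maps(signal, truth.masks, params_short)
            rim = truth.masks.labels == 2
            aucs.append(maps["AUC"].values[rim].mean())
        assert aucs[0] < aucs[1] < aucs[2]
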