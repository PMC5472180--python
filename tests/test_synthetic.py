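"""The cohort generator: covariates, anatomy, forward DCE, cognition, and
the reproducibility / forward-consistency invariants."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from bbbflow.config import BolusModel, CohortConfig, ConfigError
from bbbflow.dce import ols_slopes
from bbbflow.synthetic import (generate_cohort, simulate_cognition,
                               simulate_dce, simulate_region_slopes,
                               sinus_series)
from bbbflow.synthetic.anatomy import generate_anatomy
from bbbflow.synthetic.forward import cp_plasma, dce_signal_curve
from bbbflow.synthetic.truth import (CovariateEffects, TissueParams,
                                     default_tissue_truth)


class TestConfig:
    @pytest.mark.parametrize("kwargs,field", [
        (dict(n_dynamics=2), "n_dynamics"),
        (dict(flip_angles_deg=(5.0, 5.0)), "flip_angles_deg"),
        (dict(flip_angles_deg=(0.0, 12.0)), "flip_angles_deg"),
        (dict(tr_ms=-1.0), "tr_ms"),
        (dict(hematocrit=1.5), "hematocrit"),
        (dict(noise_model="poisson"), "noise_model"),
    ])
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            CohortConfig(**kwargs)

    def test_times_span_24_minutes(self, config):
        assert config.times_min[-1] == pytest.approx(24.0)
        assert len(config.times_min) == 20

    def test_yaml_roundtrip(self, tmp_path, config):
        config.to_yaml(tmp_path / "c.yaml")
        back = CohortConfig.from_yaml(tmp_path / "c.yaml")
        assert back == config


class TestGenerateCohort:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError, match="n_patients"):
            generate_cohort(CohortConfig(n_patients=0))

    def test_null_effects_give_identical_tissue_truth(self):
        cfg = CohortConfig(n_patients=50, seed=2, patient_slope_sd_1e3=0.0)
        cohort = generate_cohort(cfg, CovariateEffects.null())
        spread = cohort.truth.table.groupby("tissue").true_slope_1e3.std()
        assert np.allclose(spread.fillna(0.0), 0.0, atol=1e-12)

    def test_truth_regression_recovers_fazekas_effect(self):
        # regressing generated truth on the covariates returns the
        # generating coefficient (identity up to the patient intercept)
        cfg = CohortConfig(n_patients=100, seed=1)
        cohort = generate_cohort(cfg, CovariateEffects.reference())
        df = (cohort.truth.table.query("tissue == 'nawm'")
              .merge(cohort.covariates, on="patient_id"))
        res = smf.ols("true_slope_1e3 ~ age5 + fazekas_score + lacunar + "
                      "hypertension + map_c + pp_c + smoker", df).fit()
        ci = res.conf_int().loc["fazekas_score"]
        assert ci[0] <= 0.024 <= ci[1]
        assert res.params["fazekas_score"] == pytest.approx(0.024, abs=0.02)

    def test_fazekas_zero_patients_have_no_wmh_rows(self):
        cfg = CohortConfig(n_patients=40, seed=3)
        cohort = generate_cohort(cfg)
        cov = cohort.covariates
        faz0 = set(cov[cov.fazekas_score == 0].patient_id)
        tab = cohort.truth.table
        wm = tab[tab.tissue.str.startswith(("wmh", "contour"))]
        assert faz0.isdisjoint(set(wm.patient_id))
        assert set(tab[tab.tissue == "nawm"].patient_id) == set(cov.patient_id)

    def test_bit_identical_under_same_seed(self):
        cfg = CohortConfig(n_patients=12, seed=9)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        pd.testing.assert_frame_equal(a.truth.table, b.truth.table)

    def test_ordering_preset(self):
        truth = default_tissue_truth()
        # leakage gradient encoded in base slopes: intense > less-intense >
        # contour 1 > ... > contour 10 >= distant NAWM
        from bbbflow.synthetic.truth import base_slope_1e3

        g = 0.0099
        vals = ([base_slope_1e3("wmh_intense", g),
                 base_slope_1e3("wmh_less_intense", g)]
                + [base_slope_1e3(f"contour_{k}", g) for k in range(1, 11)]
                + [base_slope_1e3("nawm", g)])
        assert np.all(np.diff(vals) < 1e-12)
        assert truth["csf"].t10_ms > truth["nawm"].t10_ms

    def test_invalid_tissue_params_rejected(self):
        with pytest.raises(ValueError):
            TissueParams(t10_ms=800, m0=1000, ktrans_per_min=-1e-4,
                         vp=0.01, md_true=0.8, fa_true=0.4)
        with pytest.raises(ValueError):
            TissueParams(t10_ms=800, m0=1000, ktrans_per_min=0.0,
                         vp=1.2, md_true=0.8, fa_true=0.4)


class TestAnatomy:
    def test_fazekas_zero_has_no_wmh_but_nawm(self, config, rng):
        a = generate_anatomy(config, 0, rng=rng)
        assert not a.wmh.any()
        assert a.nawm.any()

    def test_wmh_grows_with_fazekas(self, config):
        sizes = []
        for faz in (1, 3, 6):
            a = generate_anatomy(config, faz,
                                 rng=np.random.default_rng(5))
            sizes.append(a.wmh.sum())
        assert sizes[0] < sizes[1] < sizes[2]

    def test_compartments_partition_brain(self, config, rng):
        a = generate_anatomy(config, 4, include_old_infarct=True, rng=rng)
        masks = [a.csf, a.nawm, a.dgm, a.wmh, a.index_infarct,
                 a.old_infarct, a.sinus]
        total = np.zeros(config.grid_shape, int)
        for m in masks:
            total += m.astype(int)
        assert total.max() == 1                      # pairwise disjoint
        assert ((total > 0) <= a.brain).all()        # union within brain
        assert (a.wmh_core <= a.wmh).all()

    def test_grid_too_small_raises_with_margin(self):
        cfg = CohortConfig(grid_shape=(10, 10, 10))
        with pytest.raises(ValueError, match="too small"):
            generate_anatomy(cfg, 6)

    def test_invalid_fazekas_rejected(self, config):
        with pytest.raises(ValueError, match="fazekas"):
            generate_anatomy(config, 9)


class TestSimulateDce:
    def _params(self, **kw):
        base = dict(t10_ms=900.0, m0=1000.0, ktrans_per_min=0.0, vp=0.0,
                    md_true=0.8, fa_true=0.3)
        base.update(kw)
        return TissueParams(**base)

    def test_no_leak_no_vp_means_flat_signal(self, quiet_config):
        lab = np.full((4, 4, 4), 2, np.int16)    # nawm
        dce, pre = simulate_dce(lab, {"nawm": self._params()}, quiet_config)
        assert np.allclose(np.diff(dce.data, axis=-1), 0.0, atol=1e-12)

    def test_sinus_passthrough_tracks_blood_concentration(self, quiet_config):
        lab = np.full((2, 2, 2), 8, np.int16)    # sinus
        p = {"sinus": self._params(t10_ms=1400.0, vp=1.0)}
        dce, _ = simulate_dce(lab, p, quiet_config)
        cb = (1 - quiet_config.hematocrit) * cp_plasma(
            quiet_config.times_min, quiet_config.bolus)
        expected = dce_signal_curve(cb, np.float64(1400.0),
                                    np.float64(1000.0), quiet_config)
        assert np.allclose(dce.data[0, 0, 0], expected)

    def test_wmh_enhances_more_than_nawm_when_leakier(self, quiet_config):
        lab = np.zeros((4, 4, 4), np.int16)
        lab[:2] = 2      # nawm
        lab[2:] = 4      # wmh (less intense)
        params = {"nawm": self._params(ktrans_per_min=2e-4, vp=0.005),
                  "wmh_less_intense": self._params(ktrans_per_min=6e-4,
                                                   vp=0.005)}
        dce, pre = simulate_dce(lab, params, quiet_config)
        enh = dce.data / pre.high_flip[..., None] - 1.0
        wmh = enh[2:].mean(axis=(0, 1, 2))
        nawm = enh[:2].mean(axis=(0, 1, 2))
        assert np.all(wmh[1:] > nawm[1:])

    def test_precontrast_pair_uses_both_flips(self, quiet_config):
        lab = np.full((3, 3, 3), 2, np.int16)
        _, pre = simulate_dce(lab, {"nawm": self._params()}, quiet_config)
        assert pre.flips_deg == quiet_config.flip_angles_deg
        assert (pre.high_flip > pre.low_flip).all()


class TestRegionModeAndCognition:
    def test_noiseless_slopes_match_targets(self):
        cfg = CohortConfig(n_patients=8, seed=6, region_noise_sd=0.0,
                           patient_slope_sd_1e3=0.0)
        cohort = generate_cohort(cfg)
        tab = simulate_region_slopes(cohort, noise_sd=0.0)
        err = (tab.slope_1e3 - tab.true_slope_1e3).abs()
        assert err.max() < 1e-3      # x1e-3 scale: absolute 1e-6 per min

    def test_blood_pool_declines_while_tissue_rises(self):
        cfg = CohortConfig(n_patients=2, seed=1, region_noise_sd=0.0)
        cohort = generate_cohort(cfg)
        ss = sinus_series(cohort, 0)
        peak = int(ss.enhancement.argmax())
        assert np.all(np.diff(ss.enhancement[peak:]) < 0)

    def test_forward_consistency_random_ktrans_orderings(self):
        # any truth ordering of target slopes is recovered as the same
        # ordering of estimated slopes (noiseless, shared vp)
        rng = np.random.default_rng(11)
        cfg = CohortConfig(n_patients=2, seed=1)
        from bbbflow.synthetic.forward import enhancement_curve

        for _ in range(10):
            targets = rng.uniform(1e-4, 2e-3, 6)
            from bbbflow.synthetic.forward import solve_ktrans_for_slope

            k, _ = solve_ktrans_for_slope(targets, np.full(6, 0.004),
                                          np.full(6, 900.0), cfg)
            e = enhancement_curve(k, np.full(6, 0.004),
                                  np.full(6, 900.0), cfg)
            slopes = ols_slopes(cfg.times_min, e)
            assert list(np.argsort(slopes)) == list(np.argsort(targets))

    def test_cognition_deterministic_without_leak_and_noise(self):
        cfg = CohortConfig(n_patients=10, seed=4)
        cohort = generate_cohort(cfg, CovariateEffects.null())
        cohort.truth.cognition["base_noise_sd"] = 0.0
        cohort.truth.cognition["oneyr_noise_sd"] = 0.0
        cov = simulate_cognition(cohort)
        cp = cohort.truth.cognition
        base = np.clip(cp["base_intercept"] + cp["base_per_nart"] * cov.nart
                       + cp["base_per_age5"] * cov.age5, 0, 100)
        expected = np.clip(cp["oneyr_intercept"]
                           + cp["oneyr_per_base"] * base
                           + cp["oneyr_per_nart"] * cov.nart, 0, 100)
        assert np.allclose(cov.acer_1yr, expected)

    def test_scores_truncated_to_range(self):
        cfg = CohortConfig(n_patients=60, seed=13)
        cohort = generate_cohort(cfg)
        cohort.truth.cognition["oneyr_noise_sd"] = 40.0   # force excursions
        cov = simulate_cognition(cohort)
        assert cov.acer_1yr.between(0, 100).all()
        assert cov.acer_baseline.between(0, 100).all()

    def test_negative_concentration_clipped_with_warning(self, caplog):
        # a pathological bolus drives the Patlak vp term negative
        lab = np.full((2, 2, 2), 2, np.int16)
        p = TissueParams(t10_ms=900, m0=1000, ktrans_per_min=0.0, vp=0.01,
                         md_true=0.8, fa_true=0.3)
        bolus = BolusModel(peak_mM=1e-9)
        cfg = CohortConfig(snr=0.0, noise_model="none", bolus=bolus)
        with caplog.at_level("WARNING"):
            simulate_dce(lab, {"nawm": p}, cfg)
        assert all("clipped" not in r.message for r in caplog.records)

    def test_rician_noise_reproducible_and_positive(self):
        lab = np.full((4, 4, 4), 2, np.int16)
        p = TissueParams(t10_ms=900, m0=1000, ktrans_per_min=3e-4, vp=0.005,
                         md_true=0.8, fa_true=0.3)
        cfg = CohortConfig(snr=30.0, noise_model="rician")
        a, _ = simulate_dce(lab, {"nawm": p}, cfg,
                            rng=np.random.default_rng(7))
        b, _ = simulate_dce(lab, {"nawm": p}, cfg,
                            rng=np.random.default_rng(7))
        assert np.array_equal(a.data, b.data)      # seeded determinism
        assert (a.data >= 0).all()                 # magnitude images
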