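"""Mixed-model and cognition inference: errors, equivariance, calibration,
null behaviour, consistency, and the two fitting modes."""

import numpy as np
import pandas as pd
import pytest

from bbbflow.config import CohortConfig
from bbbflow.stats import (ModelSpec, fazekas_group, fit_cognition_model,
                           fit_contour_gradient, fit_leakage_model,
                           fit_longitudinal_model, profile_by_fazekas_group)
from bbbflow.synthetic import (generate_cohort, simulate_cognition,
                               simulate_region_slopes)
from bbbflow.synthetic.truth import CovariateEffects
from bbbflow.validation import cognition_frame, null_type1_experiment


@pytest.fixture(scope="module")
def cohort_and_table():
    cfg = CohortConfig(n_patients=120, seed=21)
    cohort = generate_cohort(cfg)
    return cohort, simulate_region_slopes(cohort)


class TestLeakageModel:
    def test_single_patient_rejected(self, cohort_and_table):
        _, table = cohort_and_table
        one = table[table.patient_id == table.patient_id.iloc[0]]
        with pytest.raises(ValueError, match="2 patients"):
            fit_leakage_model(one, ModelSpec(covariate="fazekas_score"))

    def test_rank_deficient_design_lists_terms(self, cohort_and_table):
        _, table = cohort_and_table
        bad = table.copy()
        bad["dup"] = bad["map_c"]          # exact duplicate covariate
        spec = ModelSpec(covariate="fazekas_score",
                         adjusters=("map_c", "dup"))
        with pytest.raises(ValueError, match="collinear"):
            fit_leakage_model(bad, spec)

    def test_reporting_scale_equivariance(self, cohort_and_table):
        _, table = cohort_and_table
        spec = ModelSpec(covariate="fazekas_score")
        a = fit_leakage_model(table, spec)
        scaled = table.copy()
        scaled["slope_1e3"] = scaled.slope_1e3 * 10.0
        b = fit_leakage_model(scaled, spec)
        merged = a.merge(b, on="tissue", suffixes=("_a", "_b"))
        assert np.allclose(merged.estimate_b, 10.0 * merged.estimate_a,
                           rtol=1e-5)

    def test_returns_one_row_per_tissue(self, cohort_and_table):
        _, table = cohort_and_table
        out = fit_leakage_model(table, ModelSpec(covariate="age5"))
        assert sorted(out.tissue) == sorted(
            ["nawm", "dgm", "csf", "wmh", "index_infarct", "old_infarct"])
        assert ((out.ci95_low <= out.estimate)
                & (out.estimate <= out.ci95_high)).all()

    def test_type_one_error_controlled_under_null(self):
        # null generator: per-tissue Fazekas tests reject near nominal rate
        df = null_type1_experiment(n_reps=400, n_patients=100,
                                   tissues=("nawm", "dgm", "wmh"), seed=3)
        rates = df.groupby("tissue").reject_05.mean()
        assert (rates <= 0.075).all()

    def test_estimator_consistency_with_n(self):
        # RMSE of the NAWM Fazekas estimate shrinks from n=50 to n=800
        rmse = {}
        for n in (50, 800):
            ests = []
            for s in range(10):
                cfg = CohortConfig(n_patients=n, seed=1000 + s)
                cohort = generate_cohort(cfg)
                tab = simulate_region_slopes(cohort)
                out = fit_leakage_model(
                    tab, ModelSpec(covariate="fazekas_score"))
                ests.append(float(out[out.tissue == "nawm"].estimate.iloc[0]))
            rmse[n] = float(np.sqrt(np.mean((np.array(ests) - 0.024) ** 2)))
        assert rmse[800] < rmse[50]


class TestContourGradient:
    def test_flat_truth_ci_covers_zero(self):
        effects = CovariateEffects.reference()
        flat = CovariateEffects(
            beta_age5=effects.beta_age5, beta_fazekas=effects.beta_fazekas,
            beta_subtype=effects.beta_subtype,
            beta_hypertension=effects.beta_hypertension,
            contour_gradient_1e3=0.0)
        cfg = CohortConfig(n_patients=150, seed=7)
        cohort = generate_cohort(cfg, flat)
        tab = simulate_region_slopes(cohort)
        row = fit_contour_gradient(tab).iloc[0]
        assert row.ci95_low <= 0.0 <= row.ci95_high

    def test_two_contour_levels_rejected(self, cohort_and_table):
        _, table = cohort_and_table
        two = table[table.tissue.isin(["contour_1", "contour_2"])]
        with pytest.raises(ValueError, match="3 contour"):
            fit_contour_gradient(two)

    def test_no_contours_rejected(self, cohort_and_table):
        _, table = cohort_and_table
        with pytest.raises(ValueError, match="contour"):
            fit_contour_gradient(table[table.tissue == "nawm"])

    def test_sign_convention_positive_toward_wmh(self, cohort_and_table):
        _, table = cohort_and_table
        row = fit_contour_gradient(table).iloc[0]
        assert row.estimate > 0          # leak rises toward the WMH edge


class TestFazekasProfiles:
    def test_grouping_must_cover_all_scores(self, cohort_and_table):
        _, table = cohort_and_table
        with pytest.raises(ValueError, match="cover"):
            profile_by_fazekas_group(table, "slope_1e3",
                                     grouping={"low": (0, 2),
                                               "high": (5, 6)})

    def test_group_assignment(self):
        s = pd.Series([0, 2, 3, 4, 5, 6])
        assert list(fazekas_group(s)) == ["low", "low", "medium", "medium",
                                          "high", "high"]

    def test_preset_ordering_recovered_noiselessly(self):
        from bbbflow.synthetic import fig_profile_cohort

        cohort = fig_profile_cohort()
        tab = simulate_region_slopes(cohort, noise_sd=0.0)
        prof = profile_by_fazekas_group(tab, "slope_1e3")
        wide = prof.pivot(index="tissue", columns="faz_group",
                          values="adjusted_mean")
        contours = [t for t in wide.index if t.startswith("contour_")]
        assert ((wide.loc[contours, "high"]
                 >= wide.loc[contours, "low"] - 1e-9).all())

    def test_identical_truth_gives_overlapping_groups(self):
        cfg = CohortConfig(n_patients=150, seed=17)
        cohort = generate_cohort(cfg, CovariateEffects.null())
        tab = simulate_region_slopes(cohort)
        prof = profile_by_fazekas_group(tab, "slope_1e3")
        wide_lo = prof.pivot(index="tissue", columns="faz_group",
                             values="ci95_low")
        wide_hi = prof.pivot(index="tissue", columns="faz_group",
                             values="ci95_high")
        contours = [t for t in wide_lo.index if t.startswith("contour_")]
        overlap = [(wide_lo.loc[t, "high"] <= wide_hi.loc[t, "low"])
                   and (wide_lo.loc[t, "low"] <= wide_hi.loc[t, "high"])
                   for t in contours]
        assert np.mean(overlap) >= 0.9

    def test_single_group_degenerates_gracefully(self, cohort_and_table):
        _, table = cohort_and_table
        sub = table[table.fazekas_score >= 5]
        if sub.empty:
            pytest.skip("no high-burden patients in this draw")
        prof = profile_by_fazekas_group(sub, "slope_1e3")
        assert set(prof.faz_group) == {"high"}


class TestCognitionModel:
    def test_requires_minimum_patients(self):
        df = pd.DataFrame({
            "acer_1yr": [80.0] * 5, "wmh_slope_1e3": [1.0] * 5,
            "nart": [110] * 5, "fazekas_score": [2] * 5, "age5": [0] * 5,
            "hypertension": [0] * 5, "lacunar": [0, 1, 0, 1, 0],
        })
        with pytest.raises(ValueError, match=">= 20"):
            fit_cognition_model(df)

    def test_null_leak_ci_covers_zero(self):
        cfg = CohortConfig(n_patients=200, seed=31)
        effects = CovariateEffects(beta_leak_lacunar=0.0,
                                   beta_leak_cortical=0.0)
        cohort = generate_cohort(cfg, effects)
        tab = simulate_region_slopes(cohort)
        row = fit_cognition_model(cognition_frame(cohort, tab),
                                  include_baseline_acer=True,
                                  leak_col="wmh_true_slope_1e3").iloc[0]
        assert row.ci95_low <= 0.0 <= row.ci95_high

    def test_subtype_specific_pattern_recovered(self):
        # lacunar harm, no cortical effect: the interaction model finds
        # the sign pattern in the majority of replicate cohorts
        effects = CovariateEffects(beta_leak_lacunar=-3.52,
                                   beta_leak_cortical=0.0)
        hits_lac, hits_cort = 0, 0
        n_reps = 11
        for s in range(n_reps):
            cfg = CohortConfig(n_patients=200, seed=500 + s)
            cohort = generate_cohort(cfg, effects)
            tab = simulate_region_slopes(cohort)
            out = fit_cognition_model(cognition_frame(cohort, tab),
                                      leak_col="wmh_true_slope_1e3")
            lac = out[out.term == "wmh_leakage_z[lacunar]"].iloc[0]
            cort = out[out.term == "wmh_leakage_z[cortical]"].iloc[0]
            hits_lac += lac.ci95_high < 0.0
            hits_cort += cort.ci95_low <= 0.0 <= cort.ci95_high
        assert hits_lac > n_reps / 2
        assert hits_cort > n_reps / 2

    def test_ci_calibration_of_change_coefficient(self):
        # empirical 95% CI coverage for the leakage-on-change coefficient
        covered = 0
        n_reps = 200
        for s in range(n_reps):
            cfg = CohortConfig(n_patients=200, seed=9000 + s)
            cohort = generate_cohort(cfg)
            cog = simulate_cognition(cohort)
            row = fit_cognition_model(cog, include_baseline_acer=True,
                                      leak_col="wmh_true_slope_1e3").iloc[0]
            covered += row.ci95_low <= -1.89 <= row.ci95_high
        assert 0.88 <= covered / n_reps <= 0.99


class TestLongitudinalMode:
    def test_agrees_with_two_stage_on_noiseless_data(self):
        cfg = CohortConfig(n_patients=60, seed=4, region_noise_sd=0.0,
                           patient_slope_sd_1e3=0.0)
        cohort = generate_cohort(cfg)
        tab, curves = simulate_region_slopes(cohort, noise_sd=0.0,
                                             return_curves=True)
        tissues = ("nawm", "dgm", "wmh")
        lng = fit_longitudinal_model(curves, "fazekas_score",
                                     tissues=tissues)
        two = fit_leakage_model(tab, ModelSpec(covariate="fazekas_score",
                                               tissues=tissues))
        for t in tissues:
            a = float(lng[lng.tissue == t].estimate.iloc[0])
            b = float(two[two.tissue == t].estimate.iloc[0])
            assert np.sign(a) == np.sign(b)
            assert 0.4 < a / b < 2.5
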