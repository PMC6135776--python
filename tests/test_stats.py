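"""Association tests, effect estimates, cutoff scans, imputation and pooling."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats as sps

from phenonet.stats import (
    altman_correction,
    bootstrap_auc,
    cox_iqr_effect,
    cox_score_test,
    filter_cohort,
    impute,
    km_table,
    logistic_iqr_effect,
    mann_whitney_assoc,
    minp_cutoff,
    pool_median,
    rubin_pool,
)
from phenonet.synthetic import CohortConfig, generate_cohort, recruitment_manifest

IQR_NORMAL = 1.3489795003921634


def planted_cohort(n, beta=0.0, log_hr=0.0, seed=0, feature_seed=None):
    rng = np.random.default_rng(seed if feature_seed is None else feature_seed)
    feats = pd.DataFrame({"x": rng.normal(size=n)})
    config = CohortConfig(
        n_cases=n,
        beta={"x": beta / IQR_NORMAL},
        log_hazard={"x": log_hr / IQR_NORMAL},
        seed=seed,
    )
    return generate_cohort(config, feats)


class TestFilterCohort:
    def test_worked_exclusion_example(self):
        manifest = recruitment_manifest(
            {"UHCW": 90, "HGH": 40}, {"UHCW": 18, "HGH": 10}, seed=3
        )
        assert len(filter_cohort(manifest)) == 102

    def test_empty_manifest(self):
        empty = pd.DataFrame(columns=["case_id", "missing_5yr_status"])
        assert len(filter_cohort(empty)) == 0

    def test_no_flags_is_identity(self):
        manifest = recruitment_manifest({"A": 10}, {}, seed=0)
        pd.testing.assert_frame_equal(filter_cohort(manifest), manifest)


class TestMannWhitney:
    def test_exact_small_sample_p(self):
        p, r2 = mann_whitney_assoc([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_distributions_r2_near_zero(self):
        values = list(range(10)) * 2
        groups = [0] * 10 + [1] * 10
        _, r2 = mann_whitney_assoc(values, groups)
        assert r2 < 0.05

    def test_agrees_with_exhaustive_permutation(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pooled = rng.normal(size=8)
            groups = np.array([0] * 4 + [1] * 4)
            p, _ = mann_whitney_assoc(pooled, groups)
            # exhaustive two-sided permutation p over all C(8,4) splits
            obs_u = sps.mannwhitneyu(pooled[:4], pooled[4:]).statistic
            n1n2 = 16
            stats = []
            for idx in combinations(range(8), 4):
                x = pooled[list(idx)]
                y = pooled[[i for i in range(8) if i not in idx]]
                stats.append(sps.mannwhitneyu(x, y).statistic)
            stats = np.array(stats)
            p_exact = np.mean(
                np.abs(stats - n1n2 / 2) >= abs(obs_u - n1n2 / 2) - 1e-9
            )
            assert abs(p - p_exact) < 0.02

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            values = rng.normal(size=40)
            groups = np.array([0] * 20 + [1] * 20)
            pvals.append(mann_whitney_assoc(values, groups)[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            mann_whitney_assoc([1.0, 2.0], [0, 0])


class TestLogisticEffect:
    def test_formula_identity_on_scale(self):
        cohort = planted_cohort(1500, beta=1.0, seed=2)
        est = logistic_iqr_effect(cohort, "x")
        assert est.ratio_factor == pytest.approx(
            np.exp(est.extra["beta"] * est.extra["scale"]), rel=1e-12
        )
        assert est.baseline_value == pytest.approx(
            cohort["x"].quantile(0.25), abs=1e-9
        )
        assert est.ci_low <= est.ratio_factor <= est.ci_high
        assert 0.0 <= est.auc <= 1.0
        assert est.p_type == "likelihood_ratio"

    def test_null_coverage(self):
        covered = 0
        for rep in range(100):
            cohort = planted_cohort(300, beta=0.0, seed=rep)
            est = logistic_iqr_effect(cohort, "x")
            covered += est.ci_low <= 1.0 <= est.ci_high
        assert covered >= 90

    def test_planted_effect_recovered(self):
        factors = [
            np.log(logistic_iqr_effect(planted_cohort(2000, beta=1.0, seed=s), "x").ratio_factor)
            for s in range(5)
        ]
        assert np.mean(factors) == pytest.approx(1.0, abs=0.15)

    def test_adjusted_fit_reports_model_auc(self):
        cohort = planted_cohort(500, beta=1.0, seed=9)
        est = logistic_iqr_effect(
            cohort, "x", adjusters=("differentiation", "t_stage", "cohort")
        )
        assert est.adjusted and est.p_type == "likelihood_ratio"
        assert 0.5 <= est.auc <= 1.0

    def test_categorical_feature_level_change(self):
        cohort = planted_cohort(500, seed=12)
        est = logistic_iqr_effect(cohort, "t_stage")
        assert (est.baseline_value, est.changed_value) == ("pT3", "pT4")

    def test_degenerate_outcome_rejected(self):
        cohort = planted_cohort(100, seed=0)
        cohort["metastasis_5yr"] = 0
        with pytest.raises(ValueError, match="binary"):
            logistic_iqr_effect(cohort, "x")


class TestCoxEffect:
    def test_null_hazard_near_one(self):
        cohort = planted_cohort(2000, log_hr=0.0, seed=3)
        est = cox_iqr_effect(cohort, "x")
        assert 0.85 <= est.ratio_factor <= 1.15
        assert est.p_type == "score"

    def test_planted_hr_two_recovered(self):
        cohort = planted_cohort(2000, log_hr=np.log(2), seed=4)
        est = cox_iqr_effect(cohort, "x")
        assert 1.8 <= est.ratio_factor <= 2.2

    def test_null_coverage(self):
        covered = 0
        for rep in range(100):
            cohort = planted_cohort(300, log_hr=np.log(2), seed=1000 + rep)
            est = cox_iqr_effect(cohort, "x")
            covered += est.ci_low <= 2.0 <= est.ci_high
        assert covered >= 90

    def test_score_test_equals_logrank_on_binary_feature(self):
        rng = np.random.default_rng(6)
        n = 400
        group = rng.integers(0, 2, n)
        times = rng.exponential(1.0 / np.exp(0.7 * group))
        event = (times < 2.0).astype(int)
        times = np.minimum(times, 2.0) + rng.uniform(0, 1e-9, n)  # break ties
        _, p_score = cox_score_test(group, times, event)
        lr = logrank_test(
            times[group == 0], times[group == 1], event[group == 0], event[group == 1]
        )
        assert abs(p_score - lr.p_value) < 1e-6

    def test_multivariate_uses_wald(self):
        cohort = planted_cohort(400, log_hr=np.log(2), seed=8)
        est = cox_iqr_effect(cohort, "x", adjusters=("differentiation", "t_stage"))
        assert est.p_type == "wald" and est.adjusted

    def test_all_censored_rejected(self):
        cohort = planted_cohort(100, seed=0)
        cohort["dmfs_event"] = 0
        with pytest.raises(ValueError, match="censored"):
            cox_iqr_effect(cohort, "x")


class TestBootstrapAUC:
    def test_no_signal_auc_near_half(self):
        cohort = planted_cohort(600, log_hr=0.0, seed=10)
        fit_data = cohort[["x", "dmfs_time_years", "dmfs_event"]]
        auc = bootstrap_auc(fit_data, "dmfs_time_years", "dmfs_event", n_boot=40, seed=0)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_perfect_predictor_apparent_one_corrected_below(self):
        n = 60
        x = np.linspace(0, 1, n)
        fit_data = pd.DataFrame(
            {"x": x, "t": np.exp(-3 * x) + 0.01, "e": np.ones(n, dtype=int)}
        )
        auc = bootstrap_auc(fit_data, "t", "e", n_boot=20, seed=1)
        assert auc <= 1.0

    def test_corrected_between_null_and_apparent(self):
        cohort = planted_cohort(400, log_hr=np.log(2), seed=11)
        est = cox_iqr_effect(cohort, "x", n_boot=40, seed=2)
        assert 0.5 < est.auc <= est.extra["apparent_auc"] + 0.02

    def test_seed_reproducible(self):
        cohort = planted_cohort(300, log_hr=np.log(2), seed=12)
        fit_data = cohort[["x", "dmfs_time_years", "dmfs_event"]]
        a = bootstrap_auc(fit_data, "dmfs_time_years", "dmfs_event", n_boot=20, seed=5)
        b = bootstrap_auc(fit_data, "dmfs_time_years", "dmfs_event", n_boot=20, seed=5)
        assert a == b


class TestMinPCutoff:
    def test_altman_hand_value_and_properties(self):
        assert altman_correction(0.05) == pytest.approx(
            -1.63 * 0.05 * (1 + 2.35 * np.log(0.05)), abs=1e-12
        )
        assert altman_correction(0.05) == pytest.approx(0.49225, abs=1e-4)
        grid = np.linspace(1e-6, 0.0999, 200)
        corrected = np.array([altman_correction(p) for p in grid])
        assert (np.diff(corrected) > 0).all()  # monotone increasing in p_min
        assert (corrected >= grid).all()
        with pytest.raises(ValueError, match="0.1"):
            altman_correction(0.5)

    def test_constant_feature_no_admissible_cutoff(self):
        with pytest.raises(ValueError, match="no admissible cutoff"):
            minp_cutoff(np.ones(30), np.arange(1, 31, dtype=float), np.ones(30, int))

    def test_separated_groups_cutoff_recovered(self):
        for seed in range(3):
            rng = np.random.default_rng(20 + seed)
            n = 120
            feature = np.concatenate([rng.uniform(0, 0.4, n // 2),
                                      rng.uniform(0.6, 1.0, n // 2)])
            rate = np.where(feature < 0.5, 0.05, 0.6)
            times = rng.exponential(1.0 / rate)
            event = (times < 5.0).astype(int)
            times = np.minimum(times, 5.0)
            res = minp_cutoff(feature, times, event)
            assert 0.3 <= res.cutoff <= 0.65
            assert res.p_corrected >= res.p_min
            assert res.n_low + res.n_high == n

    def test_km_table_coordinates(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(2.0, 50)
        event = (times < 3).astype(int)
        groups = np.array(["a", "b"] * 25)
        km = km_table(np.minimum(times, 3), event, groups)
        assert set(km["group"]) == {"a", "b"}
        assert km["survival"].between(0, 1).all()
        for _, g in km.groupby("group"):
            assert (np.diff(g["survival"]) <= 1e-12).all()


class TestImputation:
    def test_no_missing_returns_identical_copies(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": ["x", "y"]})
        copies = impute(table, m=3, seed=0)
        assert len(copies) == 3
        for c in copies:
            pd.testing.assert_frame_equal(c, table)

    def test_mcar_preserves_marginal_mean(self):
        rng = np.random.default_rng(7)
        full = pd.DataFrame(
            {"a": rng.normal(5, 1, 500), "b": rng.normal(size=500)}
        )
        full["a"] += 0.8 * full["b"]
        observed = full.copy()
        observed.loc[rng.uniform(size=500) < 0.2, "a"] = np.nan
        copies = impute(observed, m=10, seed=1)
        imputed_mean = np.mean([c["a"].mean() for c in copies])
        assert imputed_mean == pytest.approx(observed["a"].mean(), abs=0.15)
        for c in copies:
            assert not c["a"].isna().any()

    def test_categorical_imputation_draws_observed_levels(self):
        table = pd.DataFrame({"g": ["u"] * 40 + ["v"] * 40 + [None] * 20,
                              "z": np.arange(100, dtype=float)})
        [completed] = impute(table, m=1, seed=2)
        assert set(completed["g"]) <= {"u", "v"}

    def test_fully_missing_column_rejected(self):
        table = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fully missing"):
            impute(table, m=2, seed=0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        table.loc[:9, "a"] = np.nan
        a = impute(table, m=2, seed=9)
        b = impute(table, m=2, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestRubinPool:
    def test_identical_estimates(self):
        pooled = rubin_pool([1.5, 1.5], [0.2, 0.2])
        assert pooled.estimate == 1.5
        assert pooled.between_variance == 0.0
        assert pooled.variance == pytest.approx(0.2)

    def test_hand_computed_variances(self):
        w = 0.5
        pooled = rubin_pool([1.0, 2.0, 3.0], [w, w, w])
        assert pooled.estimate == 2.0
        assert pooled.between_variance == pytest.approx(1.0, abs=1e-12)
        assert pooled.variance == pytest.approx(w + (1 + 1 / 3) * 1.0, abs=1e-12)
        assert pooled.ci_low < 2.0 < pooled.ci_high

    def test_single_imputation(self):
        pooled = rubin_pool([0.7], [0.1])
        assert pooled.estimate == 0.7
        assert pooled.variance == pytest.approx(0.1)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            rubin_pool([1.0, 2.0], [0.1])

    def test_median_pooling_for_rank_tests(self):
        p, r2 = pool_median([0.01, 0.04, 0.9], [0.1, 0.2, 0.3])
        assert p == 0.04 and r2 == 0.2
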