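"""ANCOVA, post hoc contrasts, correlations, and summary-statistic tests."""

import math

import numpy as np
import pandas as pd
import pytest

import tractfa as tf
from tractfa.stats import DEFAULT_COVARIATES, PAIRWISE_CONTRASTS


def _hand_table(n_per_group=3, seed=0):
    """Tiny 9-subject dataset for brute-force cross-checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("HC", "MDD", "BD"):
        for i in range(n_per_group):
            rows.append({
                "subject_id": f"{g}{i}",
                "group": g,
                "age": rng.uniform(30, 70),
                "gender": int(rng.random() < 0.5),
                "duration_illness": 0.0 if g == "HC" else rng.uniform(1, 20),
                "n_episodes": 0.0 if g == "HC" else rng.uniform(1, 10),
                "fa": rng.uniform(0.3, 0.6),
            })
    return pd.DataFrame(rows)


def _brute_force_f(table, outcome, covariates):
    """Partial F via explicit residual sums of squares."""
    y = table[outcome].to_numpy(float)
    covs = [table[c].to_numpy(float) for c in covariates]
    X_red = np.column_stack([np.ones(len(y))] + covs)
    X_full = np.column_stack([np.ones(len(y)),
                              (table.group == "MDD").to_numpy(float),
                              (table.group == "BD").to_numpy(float)] + covs)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r

    rss_f, rss_r = rss(X_full), rss(X_red)
    df_num = 2
    df_den = len(y) - X_full.shape[1]
    return ((rss_r - rss_f) / df_num) / (rss_f / df_den)


class TestAncova:
    def test_constant_outcome_gives_zero_f(self):
        table = _hand_table(5)
        table["fa"] = 0.5
        res = tf.ancova_group_effect(table, "fa")
        assert res.f_stat == 0.0

    def test_matches_brute_force_rss(self):
        for seed in range(5):
            table = _hand_table(4, seed=seed)
            res = tf.ancova_group_effect(table, "fa")
            assert res.f_stat == pytest.approx(
                _brute_force_f(table, "fa", DEFAULT_COVARIATES), abs=1e-10)

    def test_matches_statsmodels_partial_f(self):
        """Independent oracle: statsmodels OLS anova comparison."""
        import statsmodels.formula.api as smf

        table = _hand_table(10, seed=42).rename(columns={"fa": "y"})
        full = smf.ols("y ~ C(group, Treatment('HC')) + age + gender"
                       " + duration_illness + n_episodes", data=table).fit()
        red = smf.ols("y ~ age + gender + duration_illness + n_episodes",
                      data=table).fit()
        f_sm = full.compare_f_test(red)[0]
        res = tf.ancova_group_effect(table, "y")
        assert res.f_stat == pytest.approx(f_sm, rel=1e-9)
        # covariate t values match the full model's
        for c in DEFAULT_COVARIATES:
            assert res.covariate_t[c][0] == pytest.approx(full.tvalues[c], rel=1e-9)

    def test_zero_filled_hc_design_is_full_rank(self):
        """Duration/episodes are 0 for every HC but vary in patients; the
        ANCOVA design must still be full rank and fit cleanly."""
        table = tf.make_cohort(tf.CohortSpec(n_per_group=30, seed=1))
        res = tf.ancova_group_effect(table, "body_cc_L")
        assert np.isfinite(res.f_stat) and 0 <= res.p_value <= 1
        assert res.n_used == 90

    def test_constant_covariate_rejected_by_name(self):
        table = _hand_table(5)
        table["age"] = 50.0
        with pytest.raises(ValueError, match="age"):
            tf.ancova_group_effect(table, "fa")

    def test_group_too_small_rejected(self):
        table = _hand_table(5)
        table = table[~((table.group == "BD") & (table.index % 5 != 0))]
        with pytest.raises(ValueError, match="BD"):
            tf.ancova_group_effect(table, "fa")

    def test_family_batch_equals_individual_fits(self):
        table = tf.make_cohort(tf.CohortSpec(n_per_group=10, seed=8))
        tracts = list(tf.JHU_TRACTS_54[:6])
        fam = tf.ancova_family(table, tracts)
        for r in fam:
            single = tf.ancova_group_effect(table, r.tract)
            assert r.f_stat == pytest.approx(single.f_stat, rel=1e-10)

    def test_missing_cells_listwise_deleted(self):
        table = tf.make_cohort(tf.CohortSpec(n_per_group=10, seed=8))
        table.loc[3, "body_cc_L"] = np.nan
        res = tf.ancova_group_effect(table, "body_cc_L")
        assert res.n_used == 29


class TestFamilyCorrect:
    def test_paper_mode_threshold_is_literal_001(self):
        res = [tf.AncovaResult("t1", 1.0, 0.0009, (2, 83)),
               tf.AncovaResult("t2", 1.0, 0.0011, (2, 83))]
        out = tf.family_correct(res, n_tests=54)
        assert out[0].significant and not out[1].significant

    def test_exact_mode_threshold(self):
        res = [tf.AncovaResult("t", 1.0, 0.04, (2, 83))]
        assert tf.family_correct(res, n_tests=1, alpha=0.05, mode="exact")[0].significant
        res2 = [tf.AncovaResult("t", 1.0, 0.00095, (2, 83))]
        # 0.05 / 54 = 9.26e-4 < 0.00095
        assert not tf.family_correct(res2, n_tests=54, mode="exact")[0].significant
        res3 = [tf.AncovaResult("t", 1.0, 0.0009, (2, 83))]
        assert tf.family_correct(res3, n_tests=54, mode="exact")[0].significant


class TestPosthoc:
    def test_adjusted_p_is_three_times_unadjusted(self):
        """Direct-multiplication oracle on the hand-built dataset."""
        from scipy import stats as sps

        table = _hand_table(3, seed=1)
        ph = tf.posthoc_pairwise(table, "fa")
        # brute force: refit the full model, form the MDD-HC contrast
        y = table["fa"].to_numpy(float)
        X = np.column_stack([np.ones(9),
                             (table.group == "MDD").to_numpy(float),
                             (table.group == "BD").to_numpy(float)]
                            + [table[c].to_numpy(float) for c in DEFAULT_COVARIATES])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = 9 - X.shape[1]
        cov = (resid @ resid / df) * np.linalg.inv(X.T @ X)
        for name, c_idx in (("MDD-HC", [1]), ("BD-HC", [2])):
            c = np.zeros(X.shape[1])
            c[c_idx] = 1.0
            t = (c @ beta) / math.sqrt(c @ cov @ c)
            p_raw = 2 * sps.t.sf(abs(t), df)
            assert ph.contrasts[name][1] == pytest.approx(min(1.0, 3 * p_raw), rel=1e-9)
            assert ph.contrasts[name][0] == pytest.approx(c @ beta, rel=1e-9)

    def test_null_adjusted_p_rarely_significant(self):
        """With no group effects, adjusted p >= .05 in >= 93% of replicates."""
        hits = 0
        reps = 100
        for rep in range(reps):
            table = tf.make_cohort(tf.CohortSpec(
                n_per_group=30, effects={}, corr_target=None, seed=600 + rep))
            ph = tf.posthoc_pairwise(table, "body_cc_L")
            hits += all(p >= 0.05 for _, p in ph.contrasts.values())
        assert hits / reps >= 0.93

    def test_bd_deficit_isolated_in_high_power_regime(self):
        """A strong BD-only FA deficit: both BD contrasts significant, the
        MDD-HC contrast not, in most replicates."""
        good = 0
        reps = 50
        for rep in range(reps):
            table = tf.make_cohort(tf.CohortSpec(
                n_per_group=30, effects={("BD", "body_cc_L"): -0.05},
                corr_target=None, seed=9000 + rep))
            ph = tf.posthoc_pairwise(table, "body_cc_L")
            c = ph.contrasts
            good += (c["BD-HC"][1] < 0.05 and c["MDD-BD"][1] < 0.05
                     and c["MDD-HC"][1] >= 0.05)
        assert good / reps >= 0.80
        assert set(PAIRWISE_CONTRASTS) == {"MDD-HC", "BD-HC", "MDD-BD"}


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert tf.pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert tf.pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r1 = tf.pearson_corr(x, y).r
        r2 = tf.pearson_corr(3.0 * x + 7.0, 0.1 * y - 2.0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            tf.pearson_corr(np.ones(10), np.arange(10.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            tf.pearson_corr([1.0, 2.0], [1.0, 2.0])

    def test_p_value_matches_t_transform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = tf.pearson_corr(x, y)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r ** 2))
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-6)


class TestSummaryTests:
    def test_anova_from_printed_depression_scores(self):
        """Three-group summary ANOVA on printed questionnaire summaries."""
        f, dfb, dfw, p = tf.anova_from_summary([9.5, 9.4, 7.5], [7.5, 7.8, 6.3], [30, 30, 30])
        assert f == pytest.approx(0.735, rel=0.02)
        assert (dfb, dfw) == (2, 87)

    def test_anova_identical_means_zero(self):
        f, *_ = tf.anova_from_summary([5.0, 5.0, 5.0], [1.0, 2.0, 1.5], [10, 10, 10])
        assert f == 0.0

    def test_two_group_anova_equals_t_squared(self):
        f, *_ = tf.anova_from_summary([3.2, 8.9], [4.2, 7.8], [30, 30])
        t, *_ = tf.t_from_summary(3.2, 4.2, 30, 8.9, 7.8, 30)
        assert f == pytest.approx(t ** 2, rel=1e-12)

    def test_anova_matches_raw_data_f(self):
        """Summary ANOVA applied to per-group summaries of raw data equals
        the raw-data one-way ANOVA."""
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        groups = [rng.normal(loc, 1.0, 20) for loc in (0.0, 0.3, 0.6)]
        f_raw = sps.f_oneway(*groups).statistic
        f_sum, *_ = tf.anova_from_summary([g.mean() for g in groups],
                                          [g.std(ddof=1) for g in groups],
                                          [len(g) for g in groups])
        assert f_sum == pytest.approx(f_raw, rel=1e-10)

    def test_t_from_printed_episode_counts(self):
        t, df, p = tf.t_from_summary(3.2, 4.2, 30, 8.9, 7.8, 30)
        assert abs(t) == pytest.approx(3.555, rel=0.015)
        assert df == 58

    def test_t_equal_means_zero_and_welch_pooled_coincide(self):
        t, *_ = tf.t_from_summary(5.0, 1.0, 20, 5.0, 2.0, 20)
        assert t == 0.0
        tp, *_ = tf.t_from_summary(3.0, 1.5, 25, 4.0, 2.5, 25)
        tw, *_ = tf.t_from_summary(3.0, 1.5, 25, 4.0, 2.5, 25, welch=True)
        assert tp == pytest.approx(tw, rel=1e-12)

    def test_chi_square_gender_table(self):
        chi2, df, p = tf.chi_square_independence([[11, 19], [15, 15], [13, 17]])
        assert chi2 == pytest.approx(1.086, abs=5e-4)
        assert df == 2

    def test_chi_square_independent_margins_zero(self):
        rows = np.array([10, 20, 30])
        cols = np.array([0.4, 0.6])
        chi2, *_ = tf.chi_square_independence(np.outer(rows, cols))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_chi_square_hand_value(self):
        chi2, df, p = tf.chi_square_independence([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero row or column"):
            tf.chi_square_independence([[0, 0], [5, 5]])


class TestCalibrationHelpers:
    def test_null_calibration_small(self):
        rate = tf.stats.null_calibration(n_replicates=20, seed=1) \
            if hasattr(tf, "stats") else None
        from tractfa.stats import null_calibration
        rate = null_calibration(n_replicates=20, seed=1)
        assert 0.0 <= rate <= 0.01

    def test_power_analysis_reports_rates(self):
        from tractfa.stats import power_analysis
        out = power_analysis(n_replicates=10, seed=1)
        assert set(out) == {"power", "specificity", "posthoc_isolation",
                            "posthoc_isolation_given_flagged"}
        assert 0.0 <= out["power"] <= 1.0
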