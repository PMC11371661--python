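"""Inference layer: ANOVA/ANCOVA, chi-square, partial correlation, FDR, K-S."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from scfc.stats import (
    ancova_group_test,
    anova_oneway,
    anova_oneway_summary,
    bh_fdr,
    chi_square_independence,
    ks_normality,
    lsd_posthoc,
    lsd_posthoc_summary,
    partial_correlation,
)

# Published demographic summaries used as worked examples: per-group counts
# for binary characteristics and (n, mean, sd) for cognitive scores in a
# three-group small-vessel-disease cohort (severe, mild, controls).
GENDER_TABLE = [[34, 58, 35], [20, 48, 44]]  # male / female
DIABETES_TABLE = [[24, 49, 29], [30, 57, 50]]
HYPERLIPIDEMIA_TABLE = [[27, 41, 31], [27, 65, 48]]
SMOKING_TABLE = [[16, 26, 22], [38, 80, 57]]
HYPERTENSION_TABLE = [[40, 52, 27], [14, 54, 52]]
SDMT_SUMMARY = [(54, 26.18, 11.85), (106, 32.18, 12.43), (79, 40.42, 14.33)]
AVLT_SUMMARY = [(54, 54.96, 13.29), (106, 61.25, 12.55), (79, 64.00, 12.36)]
SCWT_SUMMARY = [(54, 179.8, 58.93), (106, 146.21, 44.79), (79, 133.53, 37.93)]
MOCA_SUMMARY = [(54, 24.39, 2.89), (106, 25.38, 3.59), (79, 26.19, 3.76)]


def anova_textbook_oracle(groups):
    """Sum-of-squares decomposition written out longhand."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, float(sps.f.sf(f, dfb, dfw))


class TestKSNormality:
    def test_statistic_agrees_with_lilliefors(self, rng):
        x = rng.standard_normal(200)
        res = ks_normality(x, n_mc=500, seed=1)
        stat_sm, _ = lilliefors(x, dist="norm")
        assert res["statistic"] == pytest.approx(stat_sm, abs=1e-12)

    def test_uniform_sample_strongly_rejected(self, rng):
        x = rng.uniform(0, 1, 500)
        res = ks_normality(x, n_mc=400, seed=2)
        assert res["p"] < 0.01

    def test_monte_carlo_null_roughly_calibrated(self):
        # rejection rate at alpha=0.1 over seeded replicates
        rng = np.random.default_rng(99)
        rej = 0
        reps = 120
        for i in range(reps):
            x = rng.standard_normal(80)
            if ks_normality(x, n_mc=200, seed=i)["p"] < 0.1:
                rej += 1
        assert 0.04 < rej / reps < 0.18

    def test_naive_p_reported_and_larger(self, rng):
        x = rng.standard_normal(150)
        res = ks_normality(x, n_mc=300, seed=3)
        assert res["p_naive"] >= res["p"] - 0.1  # naive K-S is anticonservative

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        f, _, p = anova_oneway([1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_equal_squared_t(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.5
        f, (df1, df2), p = anova_oneway(a, b)
        t, pt = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_matches_textbook_formula_oracle(self, rng):
        groups = [list(rng.standard_normal(n) + m) for n, m in [(8, 0), (12, 0.3), (10, -0.2)]]
        f, _, p = anova_oneway(*groups)
        f_o, p_o = anova_textbook_oracle(groups)
        assert f == pytest.approx(f_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)

    def test_summary_form_consistent_with_raw(self, rng):
        groups = [rng.standard_normal(9) + 0.4 * k for k in range(3)]
        f_raw, df_raw, p_raw = anova_oneway(*groups)
        summaries = [(len(g), g.mean(), g.std(ddof=1)) for g in groups]
        f_s, df_s, p_s = anova_oneway_summary(summaries)
        assert f_s == pytest.approx(f_raw, abs=1e-10)
        assert df_s == df_raw
        assert p_s == pytest.approx(p_raw, abs=1e-10)

    @pytest.mark.parametrize(
        "summary", [SDMT_SUMMARY, AVLT_SUMMARY, SCWT_SUMMARY], ids=["SDMT", "AVLT", "SCWT"]
    )
    def test_published_score_summaries_highly_significant(self, summary):
        _, _, p = anova_oneway_summary(summary)
        assert p < 0.001

    def test_published_moca_summary_matches_printed_p(self):
        _, _, p = anova_oneway_summary(MOCA_SUMMARY)
        assert p == pytest.approx(0.017, abs=0.005)

    def test_equal_means_summary(self):
        f, _, p = anova_oneway_summary([(10, 5.0, 1.0), (12, 5.0, 2.0)])
        assert f == 0.0 and p == 1.0

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway_summary([(1, 0.0, 1.0), (5, 0.0, 1.0)])
        with pytest.raises(ValueError):
            anova_oneway_summary([(5, 0.0, -1.0), (5, 0.0, 1.0)])


class TestLSD:
    def test_identical_groups_p_near_one(self):
        p = lsd_posthoc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p[0, 1] == pytest.approx(1.0)

    def test_two_groups_equals_pooled_t(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(14) + 1.0
        p = lsd_posthoc(a, b)
        _, pt = sps.ttest_ind(a, b)
        assert p[0, 1] == pytest.approx(pt, rel=1e-10)

    def test_three_group_null_type_one_error(self):
        rng = np.random.default_rng(5)
        hits = np.zeros(3)
        reps = 800
        for _ in range(reps):
            groups = [rng.standard_normal(15) for _ in range(3)]
            p = lsd_posthoc(*groups)
            hits += [p[0, 1] < 0.05, p[0, 2] < 0.05, p[1, 2] < 0.05]
        rates = hits / reps
        assert np.all((rates > 0.03) & (rates < 0.07))

    def test_moca_posthoc_pattern_matches_published(self):
        # severe vs control significant; severe vs mild and mild vs control not
        p = lsd_posthoc_summary(MOCA_SUMMARY)
        assert p[0, 2] < 0.05
        assert p[0, 1] > 0.05
        assert p[1, 2] > 0.05


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (GENDER_TABLE, 0.097),
            (DIABETES_TABLE, 0.414),
            (HYPERLIPIDEMIA_TABLE, 0.346),
            (SMOKING_TABLE, 0.762),
        ],
        ids=["gender", "diabetes", "hyperlipidemia", "smoking"],
    )
    def test_published_tables_match_printed_p(self, table, expected):
        _, df, p, small = chi_square_independence(table)
        assert df == 2
        assert p == pytest.approx(expected, abs=0.0015)
        assert not small

    def test_hypertension_below_printed_bound(self):
        _, _, p, _ = chi_square_independence(HYPERTENSION_TABLE)
        assert p < 0.001

    def test_identical_proportions_give_zero(self):
        _, _, p, _ = chi_square_independence([[10, 20], [30, 60]])
        assert p == pytest.approx(1.0)

    def test_small_expected_flagged(self):
        _, _, _, small = chi_square_independence([[1, 2], [3, 4]])
        assert small

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[1, 2]])
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            chi_square_independence([[1.5, 2], [3, 4]])


class TestAncova:
    def test_covariate_free_reduces_to_anova_and_lsd(self, rng):
        groups = {"a": rng.standard_normal(10), "b": rng.standard_normal(12) + 0.5,
                  "c": rng.standard_normal(9) - 0.2}
        y = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        res = ancova_group_test(y, labels, None, list(groups))
        f, _, p = anova_oneway(*groups.values())
        assert res.f == pytest.approx(f, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        lsd = lsd_posthoc(*groups.values())
        names = list(groups)
        for (i, j), expected in [((0, 1), lsd[0, 1]), ((0, 2), lsd[0, 2]), ((1, 2), lsd[1, 2])]:
            assert res.posthoc_p[(names[i], names[j])] == pytest.approx(expected, abs=1e-10)

    def test_matches_statsmodels_partial_f(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        n = 60
        df = pd.DataFrame(
            {
                "y": rng.standard_normal(n),
                "g": rng.choice(["a", "b", "c"], n),
                "x1": rng.standard_normal(n),
                "x2": rng.standard_normal(n),
            }
        )
        res = ancova_group_test(
            df["y"], df["g"], df[["x1", "x2"]], ["a", "b", "c"]
        )
        fit = smf.ols("y ~ C(g) + x1 + x2", data=df).fit()
        tab = anova_lm(fit, typ=3)
        assert res.f == pytest.approx(tab.loc["C(g)", "F"], rel=1e-8)
        assert res.p == pytest.approx(tab.loc["C(g)", "PR(>F)"], rel=1e-6)

    def test_adjusted_means_remove_covariate_imbalance(self, rng):
        # groups differ only through a confounder: adjustment should shrink
        # the spurious group difference
        n = 120
        g = np.repeat(["a", "b"], n // 2)
        x = np.where(g == "a", 0.0, 2.0) + rng.standard_normal(n)
        y = 3.0 * x + rng.standard_normal(n)
        res = ancova_group_test(y, g, pd.DataFrame({"x": x}), ["a", "b"])
        raw_diff = abs(res.group_means["a"] - res.group_means["b"])
        adj_diff = abs(res.adjusted_means["a"] - res.adjusted_means["b"])
        assert adj_diff < raw_diff / 3

    def test_rank_deficient_design_rejected(self, rng):
        y = rng.standard_normal(20)
        g = np.repeat(["a", "b"], 10)
        cov = pd.DataFrame({"x1": np.arange(20.0), "x2": 2 * np.arange(20.0)})
        with pytest.raises(ValueError, match="rank"):
            ancova_group_test(y, g, cov, ["a", "b"])

    def test_tiny_group_rejected(self, rng):
        y = rng.standard_normal(5)
        g = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            ancova_group_test(y, g, None, ["a", "b"])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r, df, p = partial_correlation(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert df == 28
        assert p == pytest.approx(p_sp, rel=1e-8)

    def test_exact_linear_relationship_gives_one(self, rng):
        z = rng.standard_normal((40, 2))
        x = rng.standard_normal(40)
        y = x + 2.0 * z[:, 0] - 3.0 * z[:, 1]
        r, _, p = partial_correlation(x, y, z)
        assert r == pytest.approx(1.0, abs=1e-10)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_inverse_correlation_matrix_oracle(self, rng):
        x = rng.standard_normal(50)
        z = rng.standard_normal((50, 3))
        y = 0.4 * x + rng.standard_normal(50)
        r, _, _ = partial_correlation(x, y, z)
        c = np.corrcoef(np.column_stack([x, y, z]).T)
        prec = np.linalg.inv(c)
        r_oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_matches_pingouin(self, rng):
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(45),
                "y": rng.standard_normal(45),
                "z1": rng.standard_normal(45),
                "z2": rng.standard_normal(45),
            }
        )
        df["y"] += 0.5 * df["x"]
        r, dof, p = partial_correlation(df["x"], df["y"], df[["z1", "z2"]])
        out = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert r == pytest.approx(out["r"].iloc[0], abs=1e-8)
        assert p == pytest.approx(out["p_val"].iloc[0], rel=1e-6)

    def test_missing_values_dropped_pairwise(self, rng):
        x = rng.standard_normal(30)
        y = 0.9 * x + 0.1 * rng.standard_normal(30)
        y[3] = np.nan
        r_full, df_full, _ = partial_correlation(np.delete(x, 3), np.delete(y, 3))
        r, df, _ = partial_correlation(x, y)
        assert df == df_full == 27
        assert r == pytest.approx(r_full, abs=1e-14)

    def test_insufficient_cases_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 4.0],
                                np.eye(3)[:, :2])


class TestFDR:
    def step_up_oracle(self, p):
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [0.0] * m
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            q[i] = val
            prev = val
        return q

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5], atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), self.step_up_oracle(list(p)), atol=1e-12)

    def test_monotone_in_order_statistics(self, rng):
        p = rng.uniform(0, 1, 20)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
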