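import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from scvq import reference_cohort as ref
from scvq.cohort_stats import (
    DegenerateDataError,
    chi_square_test,
    column_proportion_ztest,
    compare_groups,
    correlate,
    fit_ordinal,
    null_thresholds,
    parallel_lines_test,
)
from scvq.cohort_stats import test_normality as normality_test


class TestNormalityDispatch:
    def test_size_dispatch(self):
        rng = np.random.default_rng(0)
        assert normality_test(rng.normal(size=60))[0] == "kolmogorov-smirnov"
        assert normality_test(rng.normal(size=30))[0] == "shapiro-wilk"

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            normality_test(np.ones(20))

    def test_type_i_calibration_on_normal_draws(self):
        rng = np.random.default_rng(1)
        keep = sum(normality_test(rng.normal(size=10_000))[1] > 0.05
                   for _ in range(100))
        assert keep >= 94

    def test_power_on_skewed_draws(self):
        rng = np.random.default_rng(2)
        reject = sum(normality_test(rng.exponential(size=200))[1] < 0.05
                     for _ in range(100))
        assert reject >= 99


class TestCompareGroups:
    def test_identical_two_groups_null_identity(self):
        res = compare_groups([1.0] * 5 + [1.0] * 5, ["a"] * 5 + ["b"] * 5)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_equal_samples_t_zero(self):
        vals = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        res = compare_groups(vals, ["a"] * 4 + ["b"] * 4)
        assert res.test_name == "t-test"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_dispatch_totality(self):
        """Every (2 vs k groups) x (normal vs not) cell reaches one test."""
        rng = np.random.default_rng(3)
        n = 60
        normal = lambda: rng.normal(size=n)
        skewed = lambda: rng.lognormal(sigma=1.5, size=n)
        cases = {
            (2, True): "t-test", (2, False): "wilcoxon-w",
            (3, True): "anova", (3, False): "kruskal-wallis",
        }
        for (k, is_normal), expected in cases.items():
            draw = normal if is_normal else skewed
            vals = np.concatenate([draw() for _ in range(k)])
            labels = np.repeat([f"g{i}" for i in range(k)], n)
            res = compare_groups(vals, labels)
            assert res.test_name == expected, (k, is_normal)
            assert "normality_p" in res.trace

    def test_shifted_group_flagged_in_posthoc(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        c = rng.normal(3.0, 1, 30)
        res = compare_groups(np.concatenate([a, b, c]),
                             ["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        assert res.p < 0.05
        assert res.posthoc[("a", "c")] < 0.05
        assert res.posthoc[("b", "c")] < 0.05
        assert res.posthoc[("a", "b")] > 0.05

    def test_omnibus_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            vals = rng.normal(size=60)
            labels = np.repeat(["a", "b", "c"], 20)
            if compare_groups(vals, labels).p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_rank_test_matches_exact_permutation_oracle(self):
        """Two-sample rank-sum p at n=6 per group vs exhaustive enumeration."""
        a = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.3])
        b = np.array([2.9, 6.1, 5.5, 7.2, 4.9, 6.8])
        ranks = sps.rankdata(np.concatenate([a, b]))
        w_obs = ranks[:6].sum()
        total = list(ranks)
        null_ws = [sum(combo) for combo in itertools.combinations(total, 6)]
        mean_w = np.mean(null_ws)
        p_exact = np.mean([abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9
                           for w in null_ws])
        _, p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="exact")
        assert p_scipy == pytest.approx(p_exact, abs=1e-9)

    def test_tiny_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestChiSquare:
    def test_education_table_reproduces_published_value(self):
        res = chi_square_test(ref.EDUCATION_BY_COGNITION)
        assert res.chi2 == pytest.approx(38.777, abs=5e-4)
        assert res.df == 9 and not res.corrected

    def test_career_table_reproduces_published_value(self):
        res = chi_square_test(ref.CAREER_BY_COGNITION)
        assert res.chi2 == pytest.approx(26.920, abs=5e-4)
        assert res.df == 6

    def test_proportional_rows_give_zero(self):
        res = chi_square_test([[10, 20, 30], [20, 40, 60]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_uncorrected_path_matches_scipy_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            table = rng.integers(5, 60, size=(rng.integers(2, 5),
                                              rng.integers(2, 5)))
            res = chi_square_test(table)
            chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
            assert res.chi2_uncorrected == pytest.approx(chi2, abs=1e-10)
            assert res.p_uncorrected == pytest.approx(p, abs=1e-10)
            assert res.df == df

    def test_continuity_correction_rule(self):
        # one expected cell in [1, 5) triggers the correction on all cells
        table = np.array([[2, 30], [4, 40]])
        res = chi_square_test(table)
        assert res.corrected
        exp = res.expected
        adj = np.maximum(np.abs(table - exp) - 0.5, 0.0)
        assert res.chi2 == pytest.approx(float((adj**2 / exp).sum()))
        # matches scipy's Yates-corrected 2x2 value
        chi2_scipy, *_ = sps.chi2_contingency(table, correction=True)
        assert res.chi2 == pytest.approx(chi2_scipy, abs=1e-10)

    def test_expected_below_one_warns(self):
        with pytest.warns(UserWarning, match="exact test"):
            chi_square_test([[1, 50], [1, 60]])

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_test([[0, 5], [0, 7]])


class TestColumnProportions:
    def test_sex_nc_column_flagged(self):
        flags = column_proportion_ztest(ref.SEX_BY_COGNITION)
        assert flags[0][(0, 1)] is True  # 65/184 vs 39/180 in the NC column

    def test_identical_rows_not_flagged(self):
        flags = column_proportion_ztest([[30, 20], [30, 20]])
        assert not any(any(col.values()) for col in flags.values())

    def test_tiny_imbalance_not_flagged(self):
        flags = column_proportion_ztest([[51, 49], [49, 51]])
        assert flags[0][(0, 1)] is False


class TestCorrelate:
    def test_monotone_spearman_one(self):
        x = np.arange(10.0)
        res = correlate(x, np.exp(x), method="spearman")
        assert res.r == pytest.approx(1.0)

    def test_antitone_both_methods(self):
        x = np.linspace(0, 1, 20)
        assert correlate(x, -x, method="pearson").r == pytest.approx(-1.0)
        assert correlate(x, -x, method="spearman").r == pytest.approx(-1.0)

    def test_tied_fixture_matches_average_rank_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 7.0])  # one tie
        rx, ry = sps.rankdata(x), sps.rankdata(y)  # average ranks
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert correlate(x, y, method="spearman").r == pytest.approx(oracle)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r1 = correlate(x, y, method="spearman").r
        r2 = correlate(np.exp(x), y**3 + 5 * y, method="spearman").r
        assert r1 == pytest.approx(r2)

    def test_auto_dispatch(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=60), rng.normal(size=60)
        assert correlate(x, y).method == "pearson"
        assert correlate(rng.lognormal(sigma=2, size=60), y).method == "spearman"

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            correlate(np.ones(10), np.arange(10.0))


def simulate_proportional_odds(rng, n, beta, thresholds):
    """Draw (X, y) from logit P(Y <= j) = theta_j - x'beta."""
    p = len(beta)
    X = rng.normal(size=(n, p))
    xb = X @ np.asarray(beta)
    cum = 1.0 / (1.0 + np.exp(-(np.asarray(thresholds)[None, :] - xb[:, None])))
    cum = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
    cell = np.diff(cum, axis=1)
    u = rng.random(n)
    y = (u[:, None] > np.cumsum(cell, axis=1)[:, :-1]).sum(axis=1)
    return X, y


class TestOrdinalRegression:
    def make_frame(self, seed=0, n=800, beta=(1.0, -0.5),
                   thresholds=(-1.0, 0.0, 1.0)):
        rng = np.random.default_rng(seed)
        X, y = simulate_proportional_odds(rng, n, beta, thresholds)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["y"] = y
        return df

    def test_null_thresholds_closed_form(self):
        p = np.array([0.25, 0.35, 0.25, 0.15])
        theta = null_thresholds(p)
        cum = np.cumsum(p)[:-1]
        np.testing.assert_allclose(theta, np.log(cum / (1 - cum)))

    def test_recovers_generating_parameters(self):
        df = self.make_frame(seed=11, n=3000)
        fit = fit_ordinal(df["y"], df, covariates=["x0", "x1"])
        est = {c.name: c for c in fit.coefficients}
        assert abs(est["x0"].estimate - 1.0) < 2 * est["x0"].se
        assert abs(est["x1"].estimate + 0.5) < 2 * est["x1"].se
        assert fit.n_categories == 4 and len(fit.thresholds) == 3
        for j, t in enumerate(fit.thresholds):
            assert abs(t.estimate - (-1.0 + j)) < 3 * t.se

    def test_wald_and_ci_identities(self):
        df = self.make_frame(seed=12)
        fit = fit_ordinal(df["y"], df, covariates=["x0", "x1"])
        for term in fit.thresholds + fit.coefficients:
            assert term.wald_chi2 == pytest.approx(
                (term.estimate / term.se) ** 2
            )
            assert term.ci_low == pytest.approx(term.estimate - 1.96 * term.se)
            assert term.ci_high == pytest.approx(term.estimate + 1.96 * term.se)

    def test_negating_covariate_negates_coefficient(self):
        df = self.make_frame(seed=13)
        df["x0_neg"] = -df["x0"]
        fit1 = fit_ordinal(df["y"], df, covariates=["x0", "x1"])
        fit2 = fit_ordinal(df["y"], df, covariates=["x0_neg", "x1"])
        b1 = fit1.coefficients[0].estimate
        b2 = fit2.coefficients[0].estimate
        assert b2 == pytest.approx(-b1, rel=1e-4, abs=1e-5)

    def test_factor_reference_levels(self):
        df = self.make_frame(seed=14)
        df["sex"] = np.where(np.arange(len(df)) % 2 == 0, "male", "female")
        fit = fit_ordinal(df["y"], df, covariates=["x0"],
                          factors={"sex": "female"})
        assert fit.reference_levels == {"sex": "female"}
        assert any(c.name == "sex[male]" for c in fit.coefficients)

    def test_model_fit_lr_significant_under_effect(self):
        df = self.make_frame(seed=15)
        fit = fit_ordinal(df["y"], df, covariates=["x0", "x1"])
        assert fit.model_lr_df == 2
        assert fit.model_lr_p < 1e-6

    def test_parallel_lines_df_formula(self):
        df = self.make_frame(seed=16, beta=(1.0,), thresholds=(-0.5, 0.7))
        fit = fit_ordinal(df["y"], df, covariates=["x0"])
        p, diag = parallel_lines_test(fit)
        assert diag["df"] == 1  # (K - 2) x predictors = 1 x 1
        assert 0.0 <= p <= 1.0

    def test_parallel_lines_detects_nonparallel_slopes(self):
        rng = np.random.default_rng(17)
        n = 1000
        x = rng.normal(size=n)
        # different slope per cumulative split: beta_1 = 0, beta_2 = 2
        cum1 = 1.0 / (1.0 + np.exp(-(-0.8 - 0.0 * x)))
        cum2 = 1.0 / (1.0 + np.exp(-(0.8 - 2.0 * x)))
        cum2 = np.maximum(cum1, cum2)
        u = rng.random(n)
        y = np.where(u < cum1, 0, np.where(u < cum2, 1, 2))
        df = pd.DataFrame({"x0": x, "y": y})
        fit = fit_ordinal(df["y"], df, covariates=["x0"])
        p, _ = parallel_lines_test(fit)
        assert p < 0.05

    def test_binary_outcome_rejected(self):
        df = pd.DataFrame({"y": [0, 1] * 10, "x0": np.arange(20.0)})
        with pytest.raises(ValueError):
            fit_ordinal(df["y"], df, covariates=["x0"])
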