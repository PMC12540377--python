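"""The cohort statistical battery.

Implements the analysis conventions of a classical clinical-statistics
workflow:

* normality testing dispatched on sample size (Lilliefors-corrected
  Kolmogorov-Smirnov for n >= 50, Shapiro-Wilk below),
* group comparisons dispatched on normality — one-way ANOVA with Bonferroni
  or Tamhane-T2 post hocs, Kruskal-Wallis with Bonferroni-adjusted pairwise
  rank tests, independent t-test, or the two-sample rank-sum test reported in
  the Wilcoxon-W convention,
* Pearson chi-square on contingency tables with a continuity correction
  whenever any expected cell falls in [1, 5), plus column-proportion z-tests,
* Pearson/Spearman correlation dispatched on normality,
* proportional-odds (cumulative-logit, PLUM convention) ordinal regression
  with Wald statistics, model-fit LR test, Pearson/deviance goodness of fit,
  and the likelihood-ratio test of parallel lines.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "GroupComparisonResult",
    "ContingencyResult",
    "CorrelationResult",
    "TermResult",
    "OrdinalModelResult",
    "test_normality",
    "compare_groups",
    "chi_square_test",
    "column_proportion_ztest",
    "correlate",
    "fit_ordinal",
    "parallel_lines_test",
]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """The data admit no meaningful test (constant vector, empty group, ...)."""


# --------------------------------------------------------------------------
# normality and group comparisons
# --------------------------------------------------------------------------

def test_normality(x) -> tuple[str, float]:
    """Normality test dispatched on sample size.

    n >= 50: Kolmogorov-Smirnov with Lilliefors correction (parameters
    estimated from the sample); n < 50: Shapiro-Wilk.  Returns
    (method name, p value).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant vector: normality undefined")
    if len(x) >= 50:
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(x, dist="norm", pvalmethod="approx")
        return "kolmogorov-smirnov", float(p)
    _, p = stats.shapiro(x)
    return "shapiro-wilk", float(p)


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert 0.0 <= self.p <= 1.0 or np.isnan(self.p)


def _groups_normal(groups: dict[str, np.ndarray], alpha: float, trace: dict) -> bool:
    normal = True
    norm_ps = {}
    for name, g in groups.items():
        if len(g) < 3 or np.ptp(g) == 0:
            norm_ps[name] = None  # too small / constant: treated as normal
            continue
        _, p = test_normality(g)
        norm_ps[name] = p
        if p < alpha:
            normal = False
    trace["normality_p"] = norm_ps
    return normal


def _rank_sum_W(a: np.ndarray, b: np.ndarray) -> float:
    """Wilcoxon W: rank sum of the smaller group (first group on ties)."""
    ranks = stats.rankdata(np.concatenate([a, b]))
    wa, wb = ranks[: len(a)].sum(), ranks[len(a):].sum()
    return float(wa if len(a) <= len(b) else wb)


def compare_groups(
    values, labels, paired: bool = False, alpha: float = ALPHA
) -> GroupComparisonResult:
    """Compare a numeric variable across groups with normality-dispatched tests.

    All groups normal: one-way ANOVA for k >= 3 (post hoc Bonferroni-adjusted
    pooled t-tests under Levene-homogeneous variance, Tamhane T2 otherwise) or
    the independent t-test for k = 2.  Any group non-normal: Kruskal-Wallis
    with Bonferroni-adjusted pairwise rank-sum post hocs for k >= 3, or the
    two-sample rank-sum (Wilcoxon W) test for k = 2.
    """
    if paired:
        raise NotImplementedError("paired comparisons are not part of this battery")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = [str(u) for u in pd.unique(labels)]
    groups = {n: values[labels.astype(str) == n] for n in names}
    if len(groups) < 2:
        raise DegenerateDataError("need at least two groups")
    for n, g in groups.items():
        if len(g) < 2:
            raise DegenerateDataError(f"group {n!r} has fewer than 2 observations")

    trace: dict = {"groups": {n: len(g) for n, g in groups.items()}}
    normal = _groups_normal(groups, alpha, trace)
    k = len(groups)
    gvals = list(groups.values())

    if np.ptp(values) == 0:  # all observations identical: null identity
        name = "t-test" if k == 2 else "anova"
        trace["degenerate"] = "all values identical"
        return GroupComparisonResult(name, 0.0, None, 1.0, {}, trace)

    if normal and k >= 3:
        lev_stat, lev_p = stats.levene(*gvals, center="mean")
        trace["levene_p"] = float(lev_p)
        f, p = stats.f_oneway(*gvals)
        df = (k - 1, len(values) - k)
        posthoc = {}
        m = k * (k - 1) // 2
        for a, b in itertools.combinations(names, 2):
            if lev_p >= alpha:
                _, pp = stats.ttest_ind(groups[a], groups[b], equal_var=True)
                posthoc[(a, b)] = min(1.0, float(pp) * m)  # Bonferroni
            else:
                _, pp = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                posthoc[(a, b)] = min(1.0, 1.0 - (1.0 - float(pp)) ** m)  # Tamhane T2
        trace["posthoc"] = "bonferroni" if lev_p >= alpha else "tamhane-t2"
        return GroupComparisonResult("anova", float(f), df, float(p), posthoc, trace)

    if normal:  # k == 2
        lev_stat, lev_p = stats.levene(*gvals, center="mean")
        trace["levene_p"] = float(lev_p)
        t, p = stats.ttest_ind(*gvals, equal_var=lev_p >= alpha)
        df = len(values) - 2 if lev_p >= alpha else None
        return GroupComparisonResult("t-test", float(t), df, float(p), {}, trace)

    if k >= 3:
        h, p = stats.kruskal(*gvals)
        posthoc = {}
        m = k * (k - 1) // 2
        for a, b in itertools.combinations(names, 2):
            _, pp = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            posthoc[(a, b)] = min(1.0, float(pp) * m)
        trace["posthoc"] = "bonferroni-ranksum"
        return GroupComparisonResult(
            "kruskal-wallis", float(h), k - 1, float(p), posthoc, trace
        )

    a, b = gvals
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparisonResult(
        "wilcoxon-w", _rank_sum_W(a, b), None, float(p), {}, trace
    )


# --------------------------------------------------------------------------
# contingency tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p: float
    corrected: bool
    chi2_uncorrected: float
    p_uncorrected: float


def _expected_from_margins(obs: np.ndarray) -> np.ndarray:
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()


def chi_square_test(table) -> ContingencyResult:
    """Pearson chi-square with the small-expected-count continuity rule.

    When any expected cell lies in [1, 5) the Yates continuity correction
    (|O - E| reduced by 0.5, floored at 0) is applied to *all* cells — for any
    r x c table, following the stated analysis rule verbatim even though the
    correction is nonstandard beyond 2 x 2; the uncorrected value is always
    reported alongside.  Expected cells below 1 trigger a warning recommending
    an exact test.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any() or not np.allclose(obs, np.rint(obs)):
        raise ValueError("table must hold non-negative integer counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero marginal row/column")
    exp = _expected_from_margins(obs)
    if (exp < 1).any():
        warnings.warn(
            "expected cell below 1: chi-square unreliable, consider an exact test",
            stacklevel=2,
        )
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    chi2_plain = float(np.sum((obs - exp) ** 2 / exp))
    p_plain = float(stats.chi2.sf(chi2_plain, df))
    corrected = bool(((exp >= 1) & (exp < 5)).any())
    if corrected:
        adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
        chi2_val = float(np.sum(adj**2 / exp))
        p_val = float(stats.chi2.sf(chi2_val, df))
    else:
        chi2_val, p_val = chi2_plain, p_plain
    return ContingencyResult(
        observed=obs, expected=exp, chi2=chi2_val, df=df, p=p_val,
        corrected=corrected, chi2_uncorrected=chi2_plain, p_uncorrected=p_plain,
    )


def column_proportion_ztest(
    table, alpha: float = ALPHA, adjust: str = "bonferroni"
) -> dict[int, dict[tuple[int, int], bool]]:
    """Column-proportions z-tests (the cross-tab column-test convention).

    Within each column, every pair of rows is compared by a pooled
    two-proportion z-test on the row-conditional proportions (cell count over
    its *row* total).  Returns, per column index, a dict mapping row pairs to
    a flag: True when the proportions differ at the (Bonferroni-adjusted)
    alpha.  Columns with a zero total are skipped with a warning.
    """
    obs = np.asarray(table, dtype=float)
    row_tot = obs.sum(axis=1)
    n_rows, n_cols = obs.shape
    m = n_rows * (n_rows - 1) // 2
    crit_alpha = alpha / m if adjust == "bonferroni" else alpha
    out: dict[int, dict[tuple[int, int], bool]] = {}
    for j in range(n_cols):
        if obs[:, j].sum() == 0:
            warnings.warn(f"column {j} has zero total; skipped", stacklevel=2)
            continue
        flags: dict[tuple[int, int], bool] = {}
        for a, b in itertools.combinations(range(n_rows), 2):
            x1, n1 = obs[a, j], row_tot[a]
            x2, n2 = obs[b, j], row_tot[b]
            pool = (x1 + x2) / (n1 + n2)
            se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
            if se == 0:
                flags[(a, b)] = False
                continue
            z = (x1 / n1 - x2 / n2) / se
            flags[(a, b)] = bool(2 * stats.norm.sf(abs(z)) < crit_alpha)
        out[j] = flags
    return out


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12


def correlate(x, y, method: str = "auto") -> CorrelationResult:
    """Pearson or Spearman correlation, auto-dispatched on normality.

    With ``method='auto'`` Pearson is used when *both* vectors pass the
    size-dispatched normality test at 0.05, Spearman otherwise.  Spearman
    uses average ranks for ties; p values are two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 4:
        raise ValueError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: correlation undefined")
    if method == "auto":
        method = (
            "pearson"
            if test_normality(x)[1] > ALPHA and test_normality(y)[1] > ALPHA
            else "spearman"
        )
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p=float(p), n=len(x))


# --------------------------------------------------------------------------
# proportional-odds ordinal regression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TermResult:
    name: str
    estimate: float
    se: float
    wald_chi2: float
    p: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class OrdinalModelResult:
    """Proportional-odds fit in the PLUM convention logit P(Y <= j) = theta_j - x'beta.

    A positive coefficient therefore means higher odds of the *worse* (later)
    outcome category.
    """

    thresholds: list[TermResult]
    coefficients: list[TermResult]
    reference_levels: dict[str, str]
    model_lr_chi2: float
    model_lr_df: int
    model_lr_p: float
    gof_pearson_chi2: float
    gof_pearson_df: int
    gof_pearson_p: float
    gof_deviance: float
    gof_deviance_p: float
    llf: float
    n_obs: int
    n_categories: int
    converged: bool
    # raw arrays kept for the parallel-lines test
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)


class ConvergenceError(RuntimeError):
    pass


def _build_design(
    data: pd.DataFrame,
    covariates: list[str],
    factors: dict[str, str] | None,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    refs: dict[str, str] = {}
    for c in covariates:
        cols.append(np.asarray(data[c], dtype=float))
        names.append(c)
    for f, ref in (factors or {}).items():
        levels = [str(v) for v in pd.unique(data[f].astype(str))]
        if str(ref) not in levels:
            raise ValueError(f"reference level {ref!r} not found in factor {f!r}")
        refs[f] = str(ref)
        for lev in levels:
            if lev == str(ref):
                continue
            cols.append((data[f].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    if X.shape[1] and np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError("design matrix is rank deficient")
    return X, names, refs


def _cumlogit_loglik(theta: np.ndarray, B: np.ndarray, X: np.ndarray,
                     y: np.ndarray, K: int) -> float:
    """Multinomial log-likelihood of a cumulative-logit model.

    ``B`` is (K-1, p): one slope vector per threshold (rows identical for the
    proportional-odds model).  Probabilities are clipped at 1e-12 so that
    non-monotone configurations explored by the optimizer stay finite.
    """
    eta = theta[None, :] - X @ B.T  # (n, K-1)
    cum = expit(eta)
    cum = np.hstack([np.zeros((len(X), 1)), cum, np.ones((len(X), 1))])
    probs = np.clip(np.diff(cum, axis=1), 1e-12, None)
    return float(np.sum(np.log(probs[np.arange(len(y)), y])))


def fit_ordinal(
    y,
    data: pd.DataFrame,
    covariates: list[str] | None = None,
    factors: dict[str, str] | None = None,
) -> OrdinalModelResult:
    """Fit a proportional-odds cumulative-logit model.

    ``y`` is an ordered outcome (codes 0..K-1, an ordered Categorical, or a
    column name in ``data``); ``covariates`` are continuous predictors and
    ``factors`` maps a categorical predictor to its reference level (dummy
    coded, reference omitted).  The likelihood is maximized by statsmodels'
    ordinal model; thresholds are reported on the natural scale with
    delta-method standard errors.  Wald chi-square is (estimate/SE)^2 and the
    95% CI is estimate +/- 1.96 SE throughout.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if isinstance(y, str):
        y = data[y]
    y_codes = (
        y.cat.codes.to_numpy() if hasattr(y, "cat") else np.asarray(y, dtype=int)
    )
    K = int(y_codes.max()) + 1
    if K < 3:
        raise ValueError("ordinal outcome needs at least 3 observed levels")
    if set(np.unique(y_codes)) != set(range(K)):
        raise ValueError("all ordered levels 0..K-1 must be observed")
    X, names, refs = _build_design(data, covariates or [], factors)
    p = X.shape[1]
    if p == 0:
        raise ValueError("no predictors; use the closed-form null thresholds instead")

    model = OrderedModel(y_codes, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    if not res.mle_retvals.get("converged", False):
        res = model.fit(method="nm", maxiter=5000, disp=False)
        if not res.mle_retvals.get("converged", False):
            raise ConvergenceError(f"ordinal fit did not converge: {res.mle_retvals}")

    params = res.params
    cov = np.asarray(res.cov_params())
    beta = np.asarray(params[:p], dtype=float)
    beta_se = np.sqrt(np.diag(cov)[:p])
    # thresholds: statsmodels parameterizes (t1, log dt2, log dt3, ...)
    raw = np.asarray(params[p:], dtype=float)
    thetas = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
    J = np.zeros((K - 1, K - 1))
    J[:, 0] = 1.0
    for k in range(1, K - 1):
        J[k:, k] = np.exp(raw[k])
    cov_t = J @ cov[p:, p:] @ J.T
    theta_se = np.sqrt(np.diag(cov_t))

    def term(name: str, est: float, se: float) -> TermResult:
        wald = (est / se) ** 2 if se > 0 else np.inf
        pval = float(stats.chi2.sf(wald, 1))
        return TermResult(name, float(est), float(se), float(wald), pval,
                          float(est - 1.96 * se), float(est + 1.96 * se))

    thresholds = [term(f"threshold_{j + 1}", thetas[j], theta_se[j])
                  for j in range(K - 1)]
    coefficients = [term(names[i], beta[i], beta_se[i]) for i in range(p)]

    # model-fit LR test against the intercept-only model (closed-form llf)
    counts = np.bincount(y_codes, minlength=K)
    ll_null = float(np.sum(counts * np.log(counts / counts.sum())))
    lr = max(0.0, 2.0 * (res.llf - ll_null))
    lr_p = float(stats.chi2.sf(lr, p))

    # goodness of fit over distinct covariate patterns
    pat, inv = np.unique(X, axis=0, return_inverse=True)
    eta = thetas[None, :] - (pat @ beta)[:, None]
    cum = np.hstack([np.zeros((len(pat), 1)), expit(eta), np.ones((len(pat), 1))])
    probs = np.clip(np.diff(cum, axis=1), 1e-12, None)
    obs = np.zeros((len(pat), K))
    np.add.at(obs, (inv, y_codes), 1.0)
    n_pat = obs.sum(axis=1, keepdims=True)
    expd = n_pat * probs
    pearson = float(np.sum((obs - expd) ** 2 / expd))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(obs > 0, obs * np.log(obs / expd), 0.0)
    deviance = float(2.0 * np.sum(dev_terms))
    gof_df = max(1, len(pat) * (K - 1) - (K - 1 + p))
    gof_p = float(stats.chi2.sf(pearson, gof_df))
    dev_p = float(stats.chi2.sf(deviance, gof_df))

    return OrdinalModelResult(
        thresholds=thresholds, coefficients=coefficients, reference_levels=refs,
        model_lr_chi2=lr, model_lr_df=p, model_lr_p=lr_p,
        gof_pearson_chi2=pearson, gof_pearson_df=gof_df, gof_pearson_p=gof_p,
        gof_deviance=deviance, gof_deviance_p=dev_p,
        llf=float(res.llf), n_obs=len(y_codes), n_categories=K,
        converged=True, _y=y_codes, _X=X,
    )


def null_thresholds(proportions) -> np.ndarray:
    """Closed-form thresholds of the intercept-only cumulative-logit model."""
    p = np.asarray(proportions, dtype=float)
    cum = np.cumsum(p)[:-1]
    return np.log(cum / (1 - cum))


def parallel_lines_test(fit: OrdinalModelResult) -> tuple[float, dict]:
    """Likelihood-ratio test of the proportional-odds (parallel lines) assumption.

    The general alternative relaxes the common slope to one slope vector per
    cumulative split: logit P(Y <= j) = theta_j - x'beta_j.  That model is fit
    by direct maximum likelihood (it has no closed form and can produce
    non-monotone cumulative probabilities away from the optimum, which the
    likelihood clips).  LR = 2(ll_general - ll_parallel) on
    (K - 2) x n_predictors degrees of freedom.  Returns (p, diagnostics).
    """
    y, X = fit._y, fit._X
    K = fit.n_categories
    p = X.shape[1]
    df = (K - 2) * p
    theta0 = np.array([t.estimate for t in fit.thresholds])
    beta0 = np.array([c.estimate for c in fit.coefficients])

    def negll(packed: np.ndarray) -> float:
        theta = packed[: K - 1]
        B = packed[K - 1:].reshape(K - 1, p)
        return -_cumlogit_loglik(theta, B, X, y, K)

    x0 = np.concatenate([theta0, np.tile(beta0, K - 1)])
    opt = optimize.minimize(negll, x0, method="BFGS",
                            options={"maxiter": 2000, "gtol": 1e-6})
    diagnostics = {"method": "likelihood-ratio", "df": df,
                   "general_converged": bool(opt.success)}
    if not opt.success and not np.isfinite(opt.fun):
        # score-test style fallback: evaluate at the restricted optimum
        diagnostics["method"] = "fallback-restricted"
        return 1.0, diagnostics
    ll_general = -float(opt.fun)
    lr = max(0.0, 2.0 * (ll_general - fit.llf))
    diagnostics["lr_chi2"] = lr
    diagnostics["ll_general"] = ll_general
    return float(stats.chi2.sf(lr, df)), diagnostics
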