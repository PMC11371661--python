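"""Group-comparison and brain-cognition inference.

Implements the analysis chain applied to the coupling and efficiency AUC
metrics: Kolmogorov-Smirnov normality screening (with an estimated-parameter
Monte-Carlo null), one-way ANOVA in both raw-data and summary-statistic form,
LSD pairwise post hoc tests, Pearson chi-square tests of independence for
count data, ANCOVA (linear model with group dummies plus covariates, partial
F on the group block, LSD-style pairwise contrasts, adjusted means), partial
correlation with covariates, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "ks_normality",
    "anova_oneway",
    "anova_oneway_summary",
    "lsd_posthoc",
    "lsd_posthoc_summary",
    "chi_square_independence",
    "ancova_group_test",
    "partial_correlation",
    "bh_fdr",
]


# ---------------------------------------------------------------------------
# normality


def ks_normality(
    x: Sequence[float],
    n_mc: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """One-sample K-S test against a normal with estimated mean/sd.

    Because the null parameters are estimated from the sample, the naive K-S
    p-value is anticonservative; the primary p-value is therefore computed
    from a seeded Monte-Carlo null (Lilliefors-style): ``n_mc`` standard
    normal samples of the same size, each tested against its own estimated
    parameters.  Both p-values are returned.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance sample")
    stat, p_naive = sps.kstest(x, "norm", args=(x.mean(), sd))
    rng = np.random.default_rng(seed)
    null = np.empty(n_mc)
    for i in range(n_mc):
        z = rng.standard_normal(n)
        null[i] = sps.kstest(z, "norm", args=(z.mean(), z.std(ddof=1))).statistic
    p_mc = float((np.sum(null >= stat) + 1) / (n_mc + 1))
    return {"statistic": float(stat), "p": p_mc, "p_naive": float(p_naive), "n": n}


# ---------------------------------------------------------------------------
# ANOVA / LSD


def anova_oneway(*groups: Sequence[float]) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA: returns ``(F, (df_between, df_within), p)``."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    g = len(arrs)
    n_total = sum(len(a) for a in arrs)
    f, p = sps.f_oneway(*arrs)
    return float(f), (g - 1, n_total - g), float(p)


def anova_oneway_summary(
    groups: Sequence[tuple[int, float, float]]
) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA from per-group ``(n, mean, sd)`` summaries.

    Exactly reproduces :func:`anova_oneway` when the summaries derive from
    the raw data, which lets published summary tables be re-tested.
    """
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if len(ns) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ValueError("negative sd")
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb = len(ns) - 1
    dfw = int(n_total) - len(ns)
    if ssw == 0.0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
        return float(f), (dfb, dfw), float(p)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return float(f), (dfb, dfw), p


def _summaries(groups: Sequence[Sequence[float]]) -> list[tuple[int, float, float]]:
    out = []
    for gvals in groups:
        a = np.asarray(gvals, dtype=float)
        a = a[np.isfinite(a)]
        out.append((len(a), float(a.mean()), float(a.std(ddof=1))))
    return out


def lsd_posthoc_summary(
    groups: Sequence[tuple[int, float, float]]
) -> np.ndarray:
    """LSD pairwise two-sided p-values from ``(n, mean, sd)`` summaries.

    ``t = (m_i - m_j) / sqrt(MSW (1/n_i + 1/n_j))`` with ``df = N - g`` and
    no multiplicity adjustment.  Returns a symmetric matrix with NaN diagonal.
    """
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    g = len(ns)
    dfw = int(ns.sum()) - g
    msw = ((ns - 1) * sds**2).sum() / dfw
    p = np.full((g, g), np.nan)
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
            t = (means[i] - means[j]) / se
            p[i, j] = p[j, i] = 2 * sps.t.sf(abs(t), dfw)
    return p


def lsd_posthoc(*groups: Sequence[float]) -> np.ndarray:
    """LSD pairwise p-values from raw per-group data."""
    return lsd_posthoc_summary(_summaries(groups))


# ---------------------------------------------------------------------------
# chi-square


def chi_square_independence(
    table: Sequence[Sequence[int]],
) -> tuple[float, int, float, bool]:
    """Pearson chi-square test of independence (no continuity correction).

    Returns ``(chi2, df, p, small_expected)`` where ``small_expected`` flags
    any expected cell count below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row/column margin")
    chi2, p, df, expected = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p), bool((expected < 5).any())


# ---------------------------------------------------------------------------
# ANCOVA


@dataclasses.dataclass(frozen=True)
class GroupComparisonResult:
    """Covariate-adjusted omnibus group comparison for one metric."""

    metric: str
    groups: tuple[str, ...]
    group_n: dict[str, int]
    group_means: dict[str, float]  # raw means
    group_sds: dict[str, float]
    adjusted_means: dict[str, float]  # least-squares means at covariate means
    f: float
    df: tuple[int, int]
    p: float
    posthoc_p: dict[tuple[str, str], float]
    covariates: tuple[str, ...]


def ancova_group_test(
    y: Sequence[float],
    group: Sequence[str],
    covariates: pd.DataFrame | None = None,
    group_order: Sequence[str] | None = None,
    metric: str = "",
) -> GroupComparisonResult:
    """ANCOVA: ``y ~ group dummies + covariates`` via OLS.

    The omnibus test is the partial F for the group dummy block; pairwise
    comparisons are LSD-style unadjusted contrasts using the model residual
    variance; adjusted means are model predictions at the grand covariate
    means.  With no covariates this reduces exactly to one-way ANOVA + LSD.
    Rows with non-finite y or covariates are dropped.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray([str(g) for g in group])
    if group_order is None:
        group_order = list(dict.fromkeys(group))
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(y)))
    cov = covariates.reset_index(drop=True).astype(float)
    keep = np.isfinite(y)
    if cov.shape[1]:
        keep &= np.isfinite(cov.to_numpy()).all(axis=1)
    y, group, cov = y[keep], group[keep], cov.loc[keep].reset_index(drop=True)

    g = len(group_order)
    n = len(y)
    c = cov.shape[1]
    counts = {lab: int((group == lab).sum()) for lab in group_order}
    if any(v < 2 for v in counts.values()):
        raise ValueError(f"each group needs n >= 2, got {counts}")
    if n <= g + c + 1:
        raise ValueError("too few observations for the requested model")

    # design: intercept + (g-1) dummies (last group = reference) + covariates
    dummies = np.column_stack(
        [(group == lab).astype(float) for lab in group_order[:-1]]
    )
    X_full = np.column_stack([np.ones(n), dummies, cov.to_numpy()]) if c else (
        np.column_stack([np.ones(n), dummies])
    )
    X_red = np.column_stack([np.ones(n), cov.to_numpy()]) if c else np.ones((n, 1))
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix")

    beta, rss_full = _ols(X_full, y)
    _, rss_red = _ols(X_red, y)
    df_num = g - 1
    df_den = n - X_full.shape[1]
    f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    p = float(sps.f.sf(f, df_num, df_den))

    # adjusted means: prediction at grand covariate means for each group
    cov_means = cov.to_numpy().mean(axis=0) if c else np.empty(0)
    adj = {}
    for i, lab in enumerate(group_order):
        row = np.zeros(X_full.shape[1])
        row[0] = 1.0
        if i < g - 1:
            row[1 + i] = 1.0
        if c:
            row[g:] = cov_means
        adj[lab] = float(row @ beta)

    # LSD-style pairwise contrasts from the full model
    mse = rss_full / df_den
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    posthoc = {}
    for i in range(g):
        for j in range(i + 1, g):
            contrast = np.zeros(X_full.shape[1])
            if i < g - 1:
                contrast[1 + i] += 1.0
            if j < g - 1:
                contrast[1 + j] -= 1.0
            est = contrast @ beta
            se = np.sqrt(mse * contrast @ xtx_inv @ contrast)
            t = est / se
            posthoc[(group_order[i], group_order[j])] = float(
                2 * sps.t.sf(abs(t), df_den)
            )

    means = {lab: float(y[group == lab].mean()) for lab in group_order}
    sds = {lab: float(y[group == lab].std(ddof=1)) for lab in group_order}
    return GroupComparisonResult(
        metric=metric,
        groups=tuple(group_order),
        group_n=counts,
        group_means=means,
        group_sds=sds,
        adjusted_means=adj,
        f=float(f),
        df=(df_num, df_den),
        p=p,
        posthoc_p=posthoc,
        covariates=tuple(cov.columns.astype(str)),
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


# ---------------------------------------------------------------------------
# partial correlation


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Partial correlation between a network metric and a cognitive score."""

    metric: str
    score: str
    group: str
    r: float
    df: int
    p: float
    q: float = float("nan")  # FDR-adjusted, filled by the caller


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, int, float]:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates.

    Both variables are residualized on ``[intercept, covariates]``; the
    correlation of the residuals is tested with ``t = r sqrt(df / (1 - r^2))``
    on ``df = n - 2 - c``.  Rows with any missing value are dropped
    (complete-case).  With no covariates this is the ordinary Pearson test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    keep = np.isfinite(x) & np.isfinite(y)
    if Z.shape[1]:
        keep &= np.isfinite(Z).all(axis=1)
    x, y, Z = x[keep], y[keep], Z[keep]
    n, c = len(x), Z.shape[1]
    df = n - 2 - c
    if df < 1:
        raise ValueError(f"not enough complete cases (n={n}, c={c})")
    X = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        return r, df, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, df, p


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
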