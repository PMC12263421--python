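"""Cohort-level statistics: rank correlations, normality screening,
one-sample tests and FDR adjustment.

Questionnaire subscale scores and most behavioral indices are non-normal,
so trait-behavior association is tested with Spearman's rank correlation.
The 95% CI uses the Fisher z-transform of rho with standard error
1/sqrt(n-3); the p-value uses the t approximation with n-2 degrees of
freedom.  Missing metric values are excluded pairwise — a degenerate
subject loses individual correlations, never their whole row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationReport",
    "spearman_with_ci",
    "one_sample_test",
    "normality_screen",
    "fdr_adjust",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationReport:
    """One Spearman correlation in the reporting style rho, 95% CI, p, df."""

    x_name: str
    y_name: str
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    df: int


def spearman_with_ci(x, y, x_name="x", y_name="y") -> CorrelationReport:
    """Spearman rank correlation with Fisher-z confidence interval.

    Missing values are dropped pairwise; mid-ranks handle ties; the
    two-sided p comes from the t approximation on n-2 df.  Raises on
    constant input or fewer than 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, have {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    ci = np.tanh([z - zcrit * se, z + zcrit * se])
    return CorrelationReport(x_name=x_name, y_name=y_name, rho=rho,
                             ci_low=float(ci[0]), ci_high=float(ci[1]),
                             p_value=float(p), n_used=n, df=n - 2)


def one_sample_test(x, mu0=0.0):
    """One-sample t-test of mean(x) against mu0.

    Returns ``(t, df, p, cohens_d, (ci_low, ci_high))`` with Cohen's
    d = (mean - mu0)/SD and a 95% t-interval for the mean.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(x, popmean=mu0)
    mean = x.mean()
    d = (mean - mu0) / sd
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return (float(res.statistic), n - 1, float(res.pvalue), float(d),
            (float(mean - half), float(mean + half)))


def normality_screen(x, alpha=0.05, max_n=5000, seed=0):
    """Shapiro-Wilk screen used to justify rank-based correlation.

    Returns ``(statistic, p, is_normal)`` with ``is_normal = (p >= alpha)``.
    Samples larger than the test's validity range (n > 5000) are screened
    on a random subsample of 5000 with a logged note.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("constant vector: normality test undefined")
    if x.size > max_n:
        logger.info("normality_screen: subsampling %d of %d values for "
                    "Shapiro-Wilk", max_n, x.size)
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_n, replace=False)
    stat, p = stats.shapiro(x)
    return float(stat), float(p), bool(p >= alpha)


def fdr_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
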