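"""Sparse canonical correlation analysis via penalized matrix decomposition.

Finds sparse weight vectors x (items) and y (behavioral indices) maximizing
the cross-covariance x' Z y of the standardized cross-product matrix
Z = B' E / (n-1), subject to ||x||2 <= 1, ||y||2 <= 1 and the lasso
constraints ||x||1 <= c1, ||y||1 <= c2 with 1 <= c1 <= sqrt(p),
1 <= c2 <= sqrt(q).  The rank-1 solver alternates exact L1-ball-constrained
updates (soft-thresholding with the threshold found by bisection), so the
objective is monotone non-decreasing; successive components come from
rank-1 deflation of Z.

Penalty strengths are expressed on a (0, 1] scale mapped as
c = max(1, scale * sqrt(dim)) — the convention of penalized-matrix-
decomposition software — and are tuned by K-fold cross-validation over a
10 x 10 grid inside resampled two-thirds discovery splits.  Component
significance comes from a row-shuffle permutation test (shuffle B's rows,
refit at the same penalties) with Benjamini-Hochberg FDR across components.

Reported canonical correlations are Pearson correlations of the canonical
variates Bx and Ey; loadings are per-variable correlations with the
variate of their own set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .cohort_stats import fdr_adjust

__all__ = [
    "SCCAInputs",
    "SCCAComponent",
    "SCCAResult",
    "soft_threshold",
    "pmd_rank1",
    "scca_fit",
    "tune_penalties",
    "permutation_test",
]


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

@dataclass
class SCCAInputs:
    """Row-aligned item matrix B (n x p) and behavior matrix E (n x q),
    with the per-column standardization record."""

    B: np.ndarray
    E: np.ndarray
    b_names: list = field(default_factory=list)
    e_names: list = field(default_factory=list)
    b_mean: np.ndarray = field(init=False)
    b_sd: np.ndarray = field(init=False)
    e_mean: np.ndarray = field(init=False)
    e_sd: np.ndarray = field(init=False)

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.B.ndim != 2 or self.E.ndim != 2:
            raise ValueError("B and E must be 2-D")
        if self.B.shape[0] != self.E.shape[0]:
            raise ValueError("B and E must have the same number of rows")
        if self.B.shape[0] < 10:
            raise ValueError("need at least 10 subjects")
        if not self.b_names:
            self.b_names = [f"b{j}" for j in range(self.B.shape[1])]
        if not self.e_names:
            self.e_names = [f"e{j}" for j in range(self.E.shape[1])]
        for M, names, side in ((self.B, self.b_names, "B"),
                               (self.E, self.e_names, "E")):
            sd = M.std(axis=0, ddof=1)
            if (sd == 0).any():
                j = int(np.flatnonzero(sd == 0)[0])
                raise ValueError(
                    f"constant column in {side}: {names[j]!r}")
        self.b_mean = self.B.mean(axis=0)
        self.b_sd = self.B.std(axis=0, ddof=1)
        self.e_mean = self.E.mean(axis=0)
        self.e_sd = self.E.std(axis=0, ddof=1)

    @property
    def n(self):
        return self.B.shape[0]

    def standardized(self):
        Bs = (self.B - self.b_mean) / self.b_sd
        Es = (self.E - self.e_mean) / self.e_sd
        return Bs, Es


# ---------------------------------------------------------------------------
# Rank-1 penalized matrix decomposition
# ---------------------------------------------------------------------------

def soft_threshold(a, lam):
    """Elementwise sign(a) * max(|a| - lam, 0)."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    a = np.asarray(a, dtype=float)
    out = np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)
    return float(out) if out.ndim == 0 else out


def _l1_l2_project(u, c, n_bisect=60):
    """argmax_{||v||2<=1, ||v||1<=c} u'v, i.e. v = S(u, lam)/||S(u, lam)||2
    with the smallest lam >= 0 making the L1 constraint feasible.

    lam = 0 when the unconstrained (unit-L2) solution is already feasible;
    otherwise lam is found by bisection on (0, max|u|).  At c = 1 the
    solution is a one-hot on the largest |u| coordinate.
    """
    u = np.asarray(u, dtype=float)
    nrm = np.linalg.norm(u)
    if nrm == 0.0:
        return None
    v = u / nrm
    if np.abs(v).sum() <= c + 1e-10:
        return v
    lo, hi = 0.0, np.abs(u).max()
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        w = soft_threshold(u, mid)
        nw = np.linalg.norm(w)
        if nw == 0.0 or np.abs(w).sum() / nw > c:
            lo = mid
        else:
            hi = mid
    w = soft_threshold(u, hi)
    nw = np.linalg.norm(w)
    if nw == 0.0:
        # degenerate bisection endpoint (e.g. tied maxima at c = 1)
        v = np.zeros_like(u)
        j = int(np.argmax(np.abs(u)))
        v[j] = np.sign(u[j]) if u[j] != 0 else 1.0
        return v
    return w / nw


def pmd_rank1(Z, c1, c2, max_iter=200, tol=1e-8, init="svd",
              return_trace=False):
    """Rank-1 penalized matrix decomposition of a p x q cross-product.

    Alternates the exact L1/L2-constrained updates
    x <- argmax x'(Zy), y <- argmax (x'Z)y until the change in x falls
    below ``tol``.  Returns ``(x, y, d)`` with d = x'Zy, or
    ``(None, None, 0.0)`` for an all-zero Z (degenerate flag).  With
    ``return_trace=True`` a fourth element lists the objective after every
    alternation (non-decreasing, since each half-step is an exact
    constrained maximization).
    """
    Z = np.asarray(Z, dtype=float)
    p, q = Z.shape
    if not (1.0 - 1e-9 <= c1 <= np.sqrt(p) + 1e-9):
        raise ValueError(f"c1 must lie in [1, sqrt(p)], got {c1}")
    if not (1.0 - 1e-9 <= c2 <= np.sqrt(q) + 1e-9):
        raise ValueError(f"c2 must lie in [1, sqrt(q)], got {c2}")
    if not np.any(Z):
        return (None, None, 0.0, []) if return_trace else (None, None, 0.0)
    if isinstance(init, str) and init == "svd":
        # leading right singular vector: a warm start near the optimum
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        y = vt[0]
    else:
        y = np.asarray(init, dtype=float)
        y = y / np.linalg.norm(y)
    x = None
    trace = []
    for _ in range(max_iter):
        x_new = _l1_l2_project(Z @ y, c1)
        if x_new is None:
            break
        y_new = _l1_l2_project(Z.T @ x_new, c2)
        if y_new is None:
            break
        trace.append(float(x_new @ Z @ y_new))
        if x is not None and np.linalg.norm(x_new - x) < tol:
            x, y = x_new, y_new
            break
        x, y = x_new, y_new
    if x is None:
        return (None, None, 0.0, trace) if return_trace else (None, None, 0.0)
    d = float(x @ Z @ y)
    return (x, y, d, trace) if return_trace else (x, y, d)


# ---------------------------------------------------------------------------
# Full fits
# ---------------------------------------------------------------------------

@dataclass
class SCCAComponent:
    x: np.ndarray
    y: np.ndarray
    d: float
    canonical_correlation: float
    b_loadings: np.ndarray
    e_loadings: np.ndarray


@dataclass
class SCCAResult:
    components: list
    penalties: tuple          # (c1_scale, c2_scale)
    c1: float
    c2: float
    perm_p: np.ndarray | None = None
    perm_p_fdr: np.ndarray | None = None
    perm_warning: str | None = None

    @property
    def canonical_correlations(self):
        return np.array([c.canonical_correlation for c in self.components])


def _pearson(u, v):
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def scca_fit(inputs: SCCAInputs, c1_scale, c2_scale,
             n_components=3) -> SCCAResult:
    """Sparse CCA of standardized B against E at fixed penalty scales.

    ``c = max(1, scale * sqrt(dim))`` per side.  Components are extracted
    successively by rank-1 deflation ``Z <- Z - d x y'`` of the
    standardized cross-product ``Z = B'E/(n-1)``.  Signs are fixed by
    flipping (x, y) jointly so the B variable with the largest |loading|
    ends up positive.
    """
    if not (0.0 < c1_scale <= 1.0 and 0.0 < c2_scale <= 1.0):
        raise ValueError("penalty scales must lie in (0, 1]")
    Bs, Es = inputs.standardized()
    n, p = Bs.shape
    q = Es.shape[1]
    c1 = max(1.0, c1_scale * np.sqrt(p))
    c2 = max(1.0, c2_scale * np.sqrt(q))
    Z = Bs.T @ Es / (n - 1)
    comps = []
    for _ in range(n_components):
        x, y, d = pmd_rank1(Z, c1, c2)
        if x is None:
            break
        X = Bs @ x
        Y = Es @ y
        b_load = np.array([_pearson(Bs[:, j], X) for j in range(p)])
        e_load = np.array([_pearson(Es[:, j], Y) for j in range(q)])
        jstar = int(np.argmax(np.abs(b_load)))
        s = np.sign(x[jstar]) if x[jstar] != 0 else np.sign(b_load[jstar])
        if s < 0:
            x, y, X, Y = -x, -y, -X, -Y
            b_load, e_load = -b_load, -e_load
        comps.append(SCCAComponent(
            x=x, y=y, d=d, canonical_correlation=_pearson(X, Y),
            b_loadings=b_load, e_loadings=e_load))
        Z = Z - d * np.outer(x, y)
    return SCCAResult(components=comps, penalties=(c1_scale, c2_scale),
                      c1=c1, c2=c2)


def tune_penalties(inputs: SCCAInputs, grid=None, k_folds=10,
                   n_resamples=10, seed=0):
    """Pick penalty scales by cross-validated held-out correlation.

    For each of ``n_resamples`` random two-thirds discovery splits, run
    ``k_folds``-fold CV over the scale grid (default 0.1..1.0 in steps of
    0.1 per side) scoring the held-out Pearson correlation of the canonical
    variates; the selected point maximizes the CV score averaged over
    resamples.  Returns ``(c1_scale, c2_scale, cv_table)``.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    n = inputs.n
    n_disc = int(round(n * 2 / 3))
    if n_disc // k_folds < 3:
        raise ValueError(
            f"folds too small: {n_disc} discovery rows / {k_folds} folds")
    rng = np.random.default_rng(seed)
    scores = np.zeros((n_resamples, grid.size, grid.size))
    for r in range(n_resamples):
        disc = rng.choice(n, size=n_disc, replace=False)
        B_d, E_d = inputs.B[disc], inputs.E[disc]
        kf = KFold(n_splits=k_folds, shuffle=True,
                   random_state=int(rng.integers(2**31 - 1)))
        folds = list(kf.split(B_d))
        for i, s1 in enumerate(grid):
            for j, s2 in enumerate(grid):
                acc = 0.0
                for tr, te in folds:
                    sub = SCCAInputs(B_d[tr], E_d[tr])
                    fit = scca_fit(sub, s1, s2, n_components=1)
                    if not fit.components:
                        continue
                    comp = fit.components[0]
                    Bt = (B_d[te] - sub.b_mean) / sub.b_sd
                    Et = (E_d[te] - sub.e_mean) / sub.e_sd
                    acc += _pearson(Bt @ comp.x, Et @ comp.y)
                scores[r, i, j] = acc / len(folds)
    mean_scores = scores.mean(axis=0)
    i, j = np.unravel_index(np.argmax(mean_scores), mean_scores.shape)
    rows = [
        {"c1_scale": grid[a], "c2_scale": grid[b],
         "cv_score": mean_scores[a, b]}
        for a in range(grid.size) for b in range(grid.size)
    ]
    return float(grid[i]), float(grid[j]), pd.DataFrame(rows)


def permutation_test(inputs: SCCAInputs, fitted: SCCAResult, n_perm=5000,
                     seed=0):
    """Row-shuffle permutation test of the fitted components.

    Shuffles B's rows (holding E fixed), refits at the same penalty scales
    and component count, and compares each component's canonical
    correlation with its null distribution:
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``, followed by
    Benjamini-Hochberg adjustment across components.  The fitted result is
    updated in place and ``(perm_p, perm_p_fdr)`` returned.
    """
    rng = np.random.default_rng(seed)
    n_comp = len(fitted.components)
    if n_comp == 0:
        raise ValueError("fitted result has no components to test")
    obs = fitted.canonical_correlations
    c1s, c2s = fitted.penalties
    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        perm = rng.permutation(inputs.n)
        shuffled = SCCAInputs(inputs.B[perm], inputs.E,
                              b_names=inputs.b_names, e_names=inputs.e_names)
        null_fit = scca_fit(shuffled, c1s, c2s, n_components=n_comp)
        null_corr = np.full(n_comp, -np.inf)
        for k, comp in enumerate(null_fit.components):
            null_corr[k] = comp.canonical_correlation
        exceed += null_corr >= obs
    perm_p = (1.0 + exceed) / (1.0 + n_perm)
    perm_p_fdr = fdr_adjust(perm_p)
    fitted.perm_p = perm_p
    fitted.perm_p_fdr = perm_p_fdr
    if n_perm < 100:
        fitted.perm_warning = (
            f"only {n_perm} permutations; p-value floor is "
            f"{1.0 / (1.0 + n_perm):.3f}")
    return perm_p, perm_p_fdr
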