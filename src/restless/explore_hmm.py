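"""Tied-parameter explore/exploit hidden Markov model of bandit choices.

Four latent states underlie the choice sequence: one *explore* state (state
0) that emits choices uniformly, and one *exploit* state per arm (states
1..n_arms) that emits its own arm with probability 1.  The emission matrix
is fixed and never re-estimated.  Transitions are tied so the chain has only
two free parameters:

* ``a`` — probability of leaving any exploit state for the explore state
  (identical across exploit states);
* ``b`` — total probability of leaving the explore state, split equally
  (``b/n_arms``) across the exploit states.

Direct exploit-to-exploit transitions are structurally zero: a subject must
pass through exploration, even for a single trial, to switch arms.

Fitting is Baum-Welch EM with the tied M-step (pooled expected transition
counts over the tied entries), restarted from random (a, b) draws to escape
local maxima; decoding is Viterbi with ties broken toward lower state
indices.  Deterministic exploit emissions make many (state, choice) pairs
impossible, so all recursions use per-step scaling with explicit zero
handling rather than log(0) arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "EXPLORE",
    "TiedHMMParams",
    "HMMFit",
    "ExploreMetrics",
    "build_transition",
    "emission_matrix",
    "forward_loglik",
    "fit_baum_welch",
    "viterbi_decode",
    "explore_metrics",
]

EXPLORE = 0  # state index of the explore state; exploit_k is state k+1


@dataclass
class TiedHMMParams:
    """The chain's two free transition probabilities plus the (fixed)
    initial state distribution, uniform over the 4 states by default."""

    a: float                     # exploit -> explore
    b: float                     # explore -> any exploit (total)
    init: np.ndarray | None = None
    n_arms: int = 3

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.b <= 1.0):
            raise ValueError(
                f"transition probabilities must lie in [0, 1], "
                f"got a={self.a}, b={self.b}")
        n_states = self.n_arms + 1
        if self.init is None:
            self.init = np.full(n_states, 1.0 / n_states)
        else:
            self.init = np.asarray(self.init, dtype=float)
            if self.init.shape != (n_states,) or not np.isclose(
                    self.init.sum(), 1.0):
                raise ValueError("init must be a length-%d distribution"
                                 % n_states)


@dataclass
class HMMFit:
    """Best-of-restarts Baum-Welch fit plus the Viterbi-decoded labels."""

    params: TiedHMMParams
    transition: np.ndarray
    log_likelihood: float
    n_iterations: int
    restarts_log: np.ndarray          # final log-likelihood per restart
    labels: np.ndarray                # per-trial state, 0 = explore
    restart_traces: list = field(default_factory=list, repr=False)
    choices: np.ndarray | None = field(default=None, repr=False)
    subject_id: str | None = None


def build_transition(params: TiedHMMParams) -> np.ndarray:
    """Explicit (n_arms+1) x (n_arms+1) transition matrix of the tied chain.

    Row 0 (explore): [1-b, b/n, ..., b/n]; row k (exploit_k): ``a`` into
    explore, ``1-a`` self, exactly 0 into every other exploit state.
    """
    n = params.n_arms
    T = np.zeros((n + 1, n + 1))
    T[0, 0] = 1.0 - params.b
    T[0, 1:] = params.b / n
    for k in range(1, n + 1):
        T[k, 0] = params.a
        T[k, k] = 1.0 - params.a
    return T


def emission_matrix(n_arms: int = 3) -> np.ndarray:
    """Fixed emissions: explore is uniform over arms (maximum-entropy
    categorical); exploit_k is a one-hot on arm k. Never re-estimated."""
    E = np.zeros((n_arms + 1, n_arms))
    E[0] = 1.0 / n_arms
    for k in range(n_arms):
        E[k + 1, k] = 1.0
    return E


# ---------------------------------------------------------------------------
# Scaled recursions (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forward_core(choices, trans, emis, init):
    """Scaled forward pass; returns (loglik, alpha_hat, scales).

    alpha_hat rows are normalized to sum 1; a zero scale means the sequence
    is impossible under the parameters, signalled by loglik = -inf.
    """
    T = choices.shape[0]
    S = trans.shape[0]
    alpha = np.zeros((T, S))
    scales = np.zeros(T)
    for i in range(S):
        alpha[0, i] = init[i] * emis[i, choices[0]]
    c = alpha[0].sum()
    scales[0] = c
    if c <= 0.0:
        return -np.inf, alpha, scales
    alpha[0] /= c
    for t in range(1, T):
        for j in range(S):
            e = emis[j, choices[t]]
            if e == 0.0:
                continue
            acc = 0.0
            for i in range(S):
                acc += alpha[t - 1, i] * trans[i, j]
            alpha[t, j] = acc * e
        c = alpha[t].sum()
        scales[t] = c
        if c <= 0.0:
            return -np.inf, alpha, scales
        alpha[t] /= c
    ll = 0.0
    for t in range(T):
        ll += np.log(scales[t])
    return ll, alpha, scales


@njit(cache=True)
def _backward_core(choices, trans, emis, scales):
    T = choices.shape[0]
    S = trans.shape[0]
    beta = np.zeros((T, S))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(S):
            acc = 0.0
            for j in range(S):
                acc += trans[i, j] * emis[j, choices[t + 1]] * beta[t + 1, j]
            beta[t, i] = acc / scales[t + 1]
    return beta


@njit(cache=True)
def _tied_trans(a, b, n_arms):
    T = np.zeros((n_arms + 1, n_arms + 1))
    T[0, 0] = 1.0 - b
    for k in range(1, n_arms + 1):
        T[0, k] = b / n_arms
        T[k, 0] = a
        T[k, k] = 1.0 - a
    return T


@njit(cache=True)
def _em_core(choices, a0, b0, init, emis, n_arms, tol, max_iter):
    """Baum-Welch with the tied M-step.

    Returns (a, b, trace, n_iter): trace[i] is the log-likelihood of the
    parameters after i M-steps (trace[0] = initial params), so the returned
    (a, b) always corresponds to trace[n_iter - 1].
    """
    a = a0
    b = b0
    trace = np.empty(max_iter + 1)
    trans = _tied_trans(a, b, n_arms)
    ll, alpha, scales = _forward_core(choices, trans, emis, init)
    trace[0] = ll
    n = 1
    if not np.isfinite(ll):
        return a, b, trace[:1], 1
    T = choices.shape[0]
    S = n_arms + 1
    for _ in range(max_iter):
        beta = _backward_core(choices, trans, emis, scales)
        # pooled expected counts for the tied entries, t = 0..T-2
        num_a = 0.0
        den_a = 0.0
        num_b = 0.0
        den_b = 0.0
        for t in range(T - 1):
            # gamma[t, i] = alpha_hat * beta (already normalized per t)
            for i in range(S):
                g = alpha[t, i] * beta[t, i]
                if i == 0:
                    den_b += g
                else:
                    den_a += g
            # xi[t, i, j] normalized by the same per-t constant
            norm = 0.0
            xi_a = 0.0
            xi_b = 0.0
            for i in range(S):
                if alpha[t, i] == 0.0:
                    continue
                for j in range(S):
                    e = emis[j, choices[t + 1]]
                    if e == 0.0 or trans[i, j] == 0.0:
                        continue
                    v = alpha[t, i] * trans[i, j] * e * beta[t + 1, j]
                    norm += v
                    if i != 0 and j == 0:
                        xi_a += v
                    elif i == 0 and j != 0:
                        xi_b += v
            if norm > 0.0:
                num_a += xi_a / norm * 1.0
                num_b += xi_b / norm * 1.0
                # gamma above is alpha*beta which sums to 1 per t already
        if den_a > 0.0:
            a = min(max(num_a / den_a, 0.0), 1.0)
        if den_b > 0.0:
            b = min(max(num_b / den_b, 0.0), 1.0)
        trans = _tied_trans(a, b, n_arms)
        ll_new, alpha, scales = _forward_core(choices, trans, emis, init)
        trace[n] = ll_new
        n += 1
        if not np.isfinite(ll_new) or ll_new - ll < tol:
            break
        ll = ll_new
    return a, b, trace[:n], n


@njit(cache=True)
def _viterbi_core(choices, trans, emis, init):
    """Max-probability state path in log space; -inf marks impossible
    cells.  Ties break toward the lowest state index (first argmax), both
    for predecessors and for the final state."""
    T = choices.shape[0]
    S = trans.shape[0]
    delta = np.full((T, S), -np.inf)
    psi = np.zeros((T, S), np.int64)
    for i in range(S):
        p = init[i] * emis[i, choices[0]]
        if p > 0.0:
            delta[0, i] = np.log(p)
    for t in range(1, T):
        for j in range(S):
            e = emis[j, choices[t]]
            if e == 0.0:
                continue
            best = -np.inf
            arg = 0
            for i in range(S):
                if trans[i, j] <= 0.0 or delta[t - 1, i] == -np.inf:
                    continue
                v = delta[t - 1, i] + np.log(trans[i, j])
                if v > best:
                    best = v
                    arg = i
            if best > -np.inf:
                delta[t, j] = best + np.log(e)
                psi[t, j] = arg
    path = np.zeros(T, np.int64)
    best = -np.inf
    arg = 0
    for i in range(S):
        if delta[T - 1, i] > best:
            best = delta[T - 1, i]
            arg = i
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _choices_array(choices):
    arr = np.asarray(getattr(choices, "choices", choices), dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("choices must be a non-empty 1-D integer sequence")
    return arr


def forward_loglik(choices, params: TiedHMMParams) -> float:
    """log P(choice sequence | tied transition parameters) via the scaled
    forward recursion.  Returns -inf for sequences impossible under the
    parameters (flagged rather than raising)."""
    arr = _choices_array(choices)
    trans = build_transition(params)
    emis = emission_matrix(params.n_arms)
    ll, _, _ = _forward_core(arr, trans, emis, params.init)
    return float(ll)


def fit_baum_welch(choices, n_restarts=10, tol=1e-6, max_iter=500, seed=0,
                   n_arms=3, init=None) -> HMMFit:
    """Best-of-``n_restarts`` Baum-Welch fit of the tied (a, b) parameters.

    Restart starting points are drawn i.i.d. uniform(0.01, 0.99); the
    initial state distribution is fixed (uniform by default), leaving
    exactly the two tied transition probabilities free.  The fit with the
    highest final log-likelihood wins and is Viterbi-decoded into per-trial
    labels.
    """
    arr = _choices_array(choices)
    if arr.size < 2:
        raise ValueError("need at least 2 trials to fit transition "
                         "probabilities")
    if init is None:
        init = np.full(n_arms + 1, 1.0 / (n_arms + 1))
    emis = emission_matrix(n_arms)
    rng = np.random.default_rng(seed)
    finals = np.full(n_restarts, -np.inf)
    traces = []
    best = None
    for r in range(n_restarts):
        a0, b0 = rng.uniform(0.01, 0.99, size=2)
        a, b, trace, n_it = _em_core(arr, a0, b0, init, emis, n_arms, tol,
                                     max_iter)
        finals[r] = trace[-1]
        traces.append(trace)
        if best is None or trace[-1] > best[2]:
            best = (a, b, trace[-1], n_it)
    if best is None or not np.isfinite(best[2]):
        raise RuntimeError("all Baum-Welch restarts produced a degenerate "
                           "(zero-probability) fit")
    a, b, ll, n_it = best
    params = TiedHMMParams(a=a, b=b, init=init, n_arms=n_arms)
    trans = build_transition(params)
    labels = _viterbi_core(arr, trans, emis, params.init)
    return HMMFit(params=params, transition=trans, log_likelihood=float(ll),
                  n_iterations=int(n_it), restarts_log=finals, labels=labels,
                  restart_traces=traces, choices=arr,
                  subject_id=getattr(choices, "subject_id", None))


def viterbi_decode(choices, fit) -> np.ndarray:
    """Maximum-a-posteriori state path under fitted (or given) parameters.

    ``fit`` may be an :class:`HMMFit` or a :class:`TiedHMMParams`.  State 0
    is explore; state k labels exploitation of arm k-1 and, structurally,
    always matches the emitted choice.
    """
    arr = _choices_array(choices)
    params = fit.params if isinstance(fit, HMMFit) else fit
    trans = build_transition(params)
    emis = emission_matrix(params.n_arms)
    return _viterbi_core(arr, trans, emis, params.init)


@dataclass
class ExploreMetrics:
    p_explore: float
    p_explore_given_explore: float
    p_exploit_given_exploit: float
    exploration_potential: float


def explore_metrics(fit: HMMFit) -> ExploreMetrics:
    """Exploration summaries of a decoded label sequence.

    * ``p_explore`` — fraction of trials labeled explore;
    * ``p_explore_given_explore`` — empirical P(explore_{t+1} | explore_t);
    * ``p_exploit_given_exploit`` — empirical P(exploit_{t+1} | exploit_t),
      exploit states merged (the successor may exploit any arm);
    * ``exploration_potential`` — the fitted probability ``a`` of initiating
      exploration from exploitation.  This is this package's operational
      definition of "exploration potential" (a documented stand-in; see the
      methods note) and is configurable at the pipeline level.

    Conditional metrics are NaN when their conditioning set is empty.
    """
    labels = fit.labels
    is_exp = labels == EXPLORE
    p_explore = float(is_exp.mean())
    cur, nxt = is_exp[:-1], is_exp[1:]
    n_e = int(cur.sum())
    n_x = int((~cur).sum())
    p_ee = float((cur & nxt).sum() / n_e) if n_e else np.nan
    p_xx = float(((~cur) & (~nxt)).sum() / n_x) if n_x else np.nan
    return ExploreMetrics(
        p_explore=p_explore,
        p_explore_given_explore=p_ee,
        p_exploit_given_exploit=p_xx,
        exploration_potential=float(fit.params.a),
    )
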