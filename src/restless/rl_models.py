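"""Delta-rule reinforcement learning with an optional choice kernel.

Two nested models of trial-by-trial choice in a multi-armed bandit:

* RL: a single learning rate ``alpha`` updates the chosen arm's value
  estimate Q toward the received reward (Rescorla-Wagner delta rule), and a
  softmax with inverse temperature ``beta`` maps values to choice
  probabilities.
* RLCK: adds a choice kernel CK, a recency-weighted memory of past choices
  updated for *every* arm each trial at rate ``alpha_ck``; the softmax acts
  on ``beta * (Q + CK)``, so reward-independent perseveration competes with
  value-driven choice under a single temperature.

Likelihoods are evaluated decide-then-learn: the trial-t choice probability
uses the values *before* that trial's update.  The per-trial recursion
(`_softmax_policy` / `_update_values`) is shared verbatim with the agent
simulator in :mod:`restless.task_sim`, so simulation and likelihood cannot
drift apart.

Fitting is bounded maximum likelihood via truncated-Newton (TNC) from many
random starting points; models are compared by AIC = 2k + 2*NLL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize

__all__ = [
    "RLFit",
    "rl_nll",
    "rlck_nll",
    "value_trajectories",
    "fit_mle",
    "compare_models",
    "ALPHA_BOUNDS",
    "BETA_BOUNDS",
    "DEFAULT_Q0",
    "DEFAULT_CK0",
]

# Parameter box constraints. The lower bounds keep the softmax informative
# (alpha, alpha_ck exactly 0 is reachable to 1e-6) and the beta cap keeps
# exp(beta * Q) finite for Q on the 0/1 reward scale.
ALPHA_BOUNDS = (1e-6, 1.0)
BETA_BOUNDS = (1e-6, 50.0)

DEFAULT_Q0 = 0.5  # midpoint of the 0/1 reward scale
DEFAULT_CK0 = 0.0


# ---------------------------------------------------------------------------
# Shared per-trial recursion (also used by task_sim's agent simulator)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _softmax_policy(q, ck, beta):
    """Choice probabilities p(k) ∝ exp(beta * (Q_k + CK_k)), max-stabilized."""
    n = q.shape[0]
    p = np.empty(n)
    m = -np.inf
    for k in range(n):
        v = beta * (q[k] + ck[k])
        p[k] = v
        if v > m:
            m = v
    z = 0.0
    for k in range(n):
        p[k] = np.exp(p[k] - m)
        z += p[k]
    for k in range(n):
        p[k] /= z
    return p


@njit(cache=True)
def _update_values(q, ck, choice, reward, alpha, alpha_ck):
    """In-place delta-rule updates: chosen arm's Q; every arm's CK."""
    q[choice] += alpha * (reward - q[choice])
    for k in range(ck.shape[0]):
        ind = 1.0 if k == choice else 0.0
        ck[k] += alpha_ck * (ind - ck[k])


@njit(cache=True)
def _rlck_nll_core(choices, rewards, alpha, beta, alpha_ck, q0, ck0, n_arms):
    q = np.full(n_arms, q0)
    ck = np.full(n_arms, ck0)
    nll = 0.0
    for t in range(choices.shape[0]):
        p = _softmax_policy(q, ck, beta)
        nll -= np.log(p[choices[t]])
        _update_values(q, ck, choices[t], rewards[t], alpha, alpha_ck)
    return nll


@njit(cache=True)
def _rlck_traj_core(choices, rewards, alpha, alpha_ck, q0, ck0, n_arms):
    T = choices.shape[0]
    Q = np.empty((T + 1, n_arms))
    CK = np.empty((T + 1, n_arms))
    q = np.full(n_arms, q0)
    ck = np.full(n_arms, ck0)
    Q[0] = q
    CK[0] = ck
    for t in range(T):
        _update_values(q, ck, choices[t], rewards[t], alpha, alpha_ck)
        Q[t + 1] = q
        CK[t + 1] = ck
    return Q, CK


@njit(cache=True)
def _rlck_sim_core(probs, alpha, beta, alpha_ck, q0, ck0, u_choice, u_reward):
    """Simulate an RLCK agent on a walk using pre-drawn uniforms.

    Uses the same `_softmax_policy` / `_update_values` recursion as the
    likelihood, so simulated trajectories and likelihood trajectories are
    identical by construction.
    """
    T, n_arms = probs.shape
    choices = np.empty(T, np.int64)
    rewards = np.empty(T, np.float64)
    q = np.full(n_arms, q0)
    ck = np.full(n_arms, ck0)
    for t in range(T):
        p = _softmax_policy(q, ck, beta)
        c = n_arms - 1
        acc = 0.0
        for k in range(n_arms):
            acc += p[k]
            if u_choice[t] < acc:
                c = k
                break
        r = 1.0 if u_reward[t] < probs[t, c] else 0.0
        choices[t] = c
        rewards[t] = r
        _update_values(q, ck, c, r, alpha, alpha_ck)
    return choices, rewards


# ---------------------------------------------------------------------------
# Public likelihoods
# ---------------------------------------------------------------------------

def _check_params(alpha, beta, alpha_ck=0.0):
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not (0.0 <= alpha_ck <= 1.0):
        raise ValueError(f"alpha_ck must lie in [0, 1], got {alpha_ck}")
    if beta < 0.0 or not np.isfinite(beta):
        raise ValueError(f"beta must be finite and >= 0, got {beta}")


def _arrays(data, n_arms=None):
    choices = np.asarray(data.choices, dtype=np.int64)
    rewards = np.asarray(data.rewards, dtype=np.float64)
    if n_arms is None:
        n_arms = int(choices.max()) + 1 if choices.size else 3
        n_arms = max(n_arms, 3)
    return choices, rewards, n_arms


def rl_nll(alpha, beta, data, q0=DEFAULT_Q0, n_arms=None):
    """Negative log-likelihood of a choice sequence under the plain RL model.

    Parameters
    ----------
    alpha : float in [0, 1]
        Learning rate for the chosen arm's value update ``Q += alpha*(r-Q)``.
    beta : float >= 0
        Softmax inverse temperature.
    data : ChoiceData
        Aligned choice / reward sequences.
    q0 : float
        Initial value estimate shared by all arms.
    """
    _check_params(alpha, beta)
    choices, rewards, n_arms = _arrays(data, n_arms)
    return _rlck_nll_core(choices, rewards, alpha, beta, 0.0, q0, 0.0, n_arms)


def rlck_nll(alpha, beta, alpha_ck, data, q0=DEFAULT_Q0, ck0=DEFAULT_CK0,
             n_arms=None):
    """Negative log-likelihood under the RL + choice-kernel model.

    The kernel CK(k) relaxes toward 1 for the chosen arm and toward 0 for
    every other arm at rate ``alpha_ck``; the policy is
    ``p(k) ∝ exp(beta*(Q_k + CK_k))`` with a single shared temperature.
    With ``alpha_ck=0`` and ``ck0=0`` this reduces exactly to :func:`rl_nll`.
    """
    _check_params(alpha, beta, alpha_ck)
    choices, rewards, n_arms = _arrays(data, n_arms)
    return _rlck_nll_core(choices, rewards, alpha, beta, alpha_ck, q0, ck0,
                          n_arms)


def value_trajectories(alpha, alpha_ck, data, q0=DEFAULT_Q0, ck0=DEFAULT_CK0,
                       n_arms=None):
    """(T+1)-step Q and CK trajectories implied by a fixed choice/reward
    sequence; row t holds the values *entering* trial t."""
    _check_params(alpha, 0.0, alpha_ck)
    choices, rewards, n_arms = _arrays(data, n_arms)
    return _rlck_traj_core(choices, rewards, alpha, alpha_ck, q0, ck0, n_arms)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting and model comparison
# ---------------------------------------------------------------------------

@dataclass
class RLFit:
    """One subject's maximum-likelihood fit for one model."""

    model: str                      # "RL" or "RLCK"
    alpha: float
    beta: float
    alpha_ck: float | None
    nll: float
    aic: float
    n_restarts_used: int
    converged: bool
    best_restart_seed: int
    subject_id: str | None = None

    @property
    def n_params(self) -> int:
        return 2 if self.model == "RL" else 3


def fit_mle(model, data, n_restarts=30, bounds=None, seed=0,
            q0=DEFAULT_Q0, ck0=DEFAULT_CK0, n_arms=None):
    """Fit RL or RLCK by bounded truncated-Newton MLE with random restarts.

    Each restart draws a uniform starting point inside the parameter box and
    minimizes the model NLL with scipy's TNC method; the lowest final NLL
    wins.  Fully deterministic given ``seed``.

    Returns an :class:`RLFit`; if every restart fails the fit is returned
    with ``converged=False`` and NaN parameters (the subject is retained).
    """
    if model not in ("RL", "RLCK"):
        raise ValueError(f"model must be 'RL' or 'RLCK', got {model!r}")
    choices, rewards, n_arms = _arrays(data, n_arms)
    k = 2 if model == "RL" else 3
    if bounds is None:
        bounds = [ALPHA_BOUNDS, BETA_BOUNDS] + ([ALPHA_BOUNDS] if k == 3 else [])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    if model == "RL":
        def obj(theta):
            return _rlck_nll_core(choices, rewards, theta[0], theta[1], 0.0,
                                  q0, 0.0, n_arms)
    else:
        def obj(theta):
            return _rlck_nll_core(choices, rewards, theta[0], theta[1],
                                  theta[2], q0, ck0, n_arms)

    rng = np.random.default_rng(seed)
    best = None
    best_i = -1
    any_ok = False
    for i in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(obj, x0, method="TNC", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        any_ok = True
        if best is None or res.fun < best.fun:
            best = res
            best_i = i
    if not any_ok:
        return RLFit(model=model, alpha=np.nan, beta=np.nan,
                     alpha_ck=np.nan if k == 3 else None, nll=np.nan,
                     aic=np.nan, n_restarts_used=n_restarts, converged=False,
                     best_restart_seed=-1,
                     subject_id=getattr(data, "subject_id", None))
    theta = best.x
    nll = float(best.fun)
    return RLFit(
        model=model,
        alpha=float(theta[0]),
        beta=float(theta[1]),
        alpha_ck=float(theta[2]) if k == 3 else None,
        nll=nll,
        aic=2.0 * k + 2.0 * nll,
        n_restarts_used=n_restarts,
        converged=bool(best.success),
        best_restart_seed=best_i,
        subject_id=getattr(data, "subject_id", None),
    )


def compare_models(fits_rl, fits_rlck):
    """Per-subject and summed AIC comparison of the nested RL / RLCK fits.

    Returns ``(table, delta_aic)`` where ``delta_aic = sum AIC(RL) - sum
    AIC(RLCK)``; positive values favor the choice-kernel model.
    """
    if len(fits_rl) != len(fits_rlck):
        raise ValueError("fit lists must cover the same subjects")
    rows = []
    for f_rl, f_ck in zip(fits_rl, fits_rlck):
        if f_rl.subject_id != f_ck.subject_id:
            raise ValueError(
                f"subject mismatch: {f_rl.subject_id!r} vs {f_ck.subject_id!r}")
        rows.append({
            "subject": f_rl.subject_id,
            "aic_rl": f_rl.aic,
            "aic_rlck": f_ck.aic,
            "delta_aic": f_rl.aic - f_ck.aic,
        })
    table = pd.DataFrame(rows)
    delta = float(table["aic_rl"].sum() - table["aic_rlck"].sum())
    return table, delta
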