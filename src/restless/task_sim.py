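"""Restless-bandit task simulation and synthetic cohorts.

The task is a three-armed bandit played for 300 trials whose per-arm reward
probabilities follow independent bounded random walks (the "restless
walk"): each trial each arm steps +/-0.2 with hazard 0.6667, constrained to
[0.1, 0.9].  Steps that would leave the bounds are reflected (forced in the
feasible direction) by default, preserving per-trial volatility at the
edges; clipping is available as an option.

Agents:

* RLCK agents choose by the softmax-over-(Q + choice kernel) policy of
  :mod:`restless.rl_models`; simulation and likelihood share one per-trial
  recursion, so a simulated agent's trajectory is exactly the one the
  likelihood integrates over.
* HMM-generative agents emit choices from the tied explore/exploit chain of
  :mod:`restless.explore_hmm` (deterministic in exploit states, uniform in
  the explore state), returning the true latent states for label-accuracy
  studies.
* Outcome-independent shift agents switch arms with a fixed probability
  regardless of reward; they realize the null of the punishment-sensitivity
  statistic.

Cohorts: per-subject latent traits (aloof / rigid / pragmatic) are drawn
from a correlated Gaussian; the aloof trait is linked to the RLCK
parameters (log-link for beta, logit-link for the rates) so questionnaire
scores and bandit behavior covary by construction; 36 ordinal items (12 per
subscale, scored 1-6) load on the traits; response times are log-normal
with an additive slow-down on shift trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .explore_hmm import TiedHMMParams, build_transition
from .rl_models import _rlck_sim_core

__all__ = [
    "RewardWalk",
    "ChoiceData",
    "AgentParams",
    "CohortConfig",
    "ItemMatrix",
    "Cohort",
    "generate_walk",
    "simulate_rlck_agent",
    "simulate_hmm_agent",
    "simulate_shift_agent",
    "generate_items",
    "generate_cohort",
    "write_cohort",
    "SUBSCALES",
]

SUBSCALES = ("aloof", "rigid", "pragmatic")
ITEMS_PER_SUBSCALE = 12
N_ITEMS = ITEMS_PER_SUBSCALE * len(SUBSCALES)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RewardWalk:
    """Per-trial, per-arm reward probabilities for one session."""

    probs: np.ndarray                 # (n_trials, n_arms)
    hazard: float
    step: float
    bounds: tuple[float, float]
    seed: object = None

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    @property
    def n_arms(self) -> int:
        return self.probs.shape[1]


@dataclass
class ChoiceData:
    """One subject's aligned choice / reward / response-time sequences."""

    choices: np.ndarray
    rewards: np.ndarray
    rts: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.float64)
        if self.choices.shape != self.rewards.shape:
            raise ValueError("choices and rewards must have equal length")
        if not np.isin(self.rewards, (0.0, 1.0)).all():
            raise ValueError("rewards must be binary 0/1")
        if self.rts is not None:
            self.rts = np.asarray(self.rts, dtype=np.float64)
            if self.rts.shape != self.choices.shape:
                raise ValueError("rts must align with choices")
            if not (self.rts > 0).all():
                raise ValueError("rts must be positive")

    @property
    def n_trials(self) -> int:
        return self.choices.shape[0]


@dataclass
class AgentParams:
    """RLCK agent parameters; with alpha_ck=0 this is a plain RL agent."""

    alpha: float
    beta: float
    alpha_ck: float = 0.0
    q0: float = 0.5
    ck0: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.alpha_ck <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")


@dataclass
class ItemMatrix:
    """n_subjects x 36 integer item scores (1-6), 12 items per subscale
    in the fixed order aloof, rigid, pragmatic."""

    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_ITEMS:
            raise ValueError(f"scores must be (n_subjects, {N_ITEMS})")
        if self.scores.min() < 1 or self.scores.max() > 6:
            raise ValueError("item scores must lie in 1..6")

    @property
    def subscale_index(self) -> dict:
        return {j: SUBSCALES[j // ITEMS_PER_SUBSCALE] for j in range(N_ITEMS)}

    def subscale_sums(self) -> pd.DataFrame:
        sums = {
            name: self.scores[:, i * ITEMS_PER_SUBSCALE:
                              (i + 1) * ITEMS_PER_SUBSCALE].sum(axis=1)
            for i, name in enumerate(SUBSCALES)
        }
        df = pd.DataFrame(sums)
        df["total"] = df.sum(axis=1)
        return df


def _spd_default():
    c = np.full((3, 3), 0.4)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class CohortConfig:
    """Everything needed to generate one synthetic cohort.

    ``coupling`` maps the latent aloof trait (a z-score) to the RLCK
    parameters through monotone links: logit for the learning rates, log
    for the inverse temperature.  The defaults plant the qualitative
    trait-behavior structure this pipeline is built to detect: more aloof
    subjects get higher beta and choice-kernel rate and a slightly lower
    learning rate, hence fewer shifts and less exploration.
    """

    n_subjects: int = 100
    n_trials: int = 300
    n_arms: int = 3
    hazard: float = 0.6667
    step: float = 0.2
    bounds: tuple[float, float] = (0.1, 0.9)
    boundary: str = "reflect"
    trait_loadings: float | tuple = 0.8
    item_noise_sd: float = 0.8
    trait_correlations: np.ndarray = field(default_factory=_spd_default)
    coupling: dict = field(default_factory=lambda: {
        "alpha": -0.08, "beta": 0.13, "alpha_ck": 0.17})
    base_params: dict = field(default_factory=lambda: {
        "alpha": 0.4, "beta": 4.0, "alpha_ck": 0.3})
    param_noise_sd: dict = field(default_factory=lambda: {
        "alpha": 0.6, "beta": 0.5, "alpha_ck": 0.7})
    rt_model: tuple[float, float, float] = (np.log(0.6), 0.4, 0.15)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        corr = np.asarray(self.trait_correlations, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ValueError("trait_correlations must be a symmetric 3x3 "
                             "matrix")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ValueError("trait_correlations must be positive-definite")
        self.trait_correlations = corr


@dataclass
class Cohort:
    """A generated cohort: one ChoiceData and walk per subject, the item
    matrix, the latent traits and the per-subject generating parameters."""

    subjects: list
    walks: list
    items: ItemMatrix
    traits: np.ndarray                # (n, 3): aloof, rigid, pragmatic
    params: pd.DataFrame              # alpha, beta, alpha_ck per subject
    config: CohortConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# Reward walks
# ---------------------------------------------------------------------------

def generate_walk(n_trials=300, n_arms=3, hazard=0.6667, step=0.2,
                  bounds=(0.1, 0.9), seed=None, boundary="reflect"
                  ) -> RewardWalk:
    """Generate one restless walk.

    Per arm independently, the reward probability starts uniformly on the
    grid {lo, lo+step, ..., hi} and on every later trial steps +/-``step``
    with probability ``hazard`` (direction uniform), otherwise holds.
    With ``boundary='reflect'`` a step that would exit [lo, hi] is forced
    in the feasible direction; ``'clip'`` truncates it at the bound.
    """
    lo, hi = bounds
    if not (0.0 <= hazard <= 1.0):
        raise ValueError(f"hazard must lie in [0, 1], got {hazard}")
    if step <= 0.0:
        raise ValueError("step must be positive")
    if not lo < hi:
        raise ValueError(f"bounds must satisfy lo < hi, got {bounds}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if boundary not in ("reflect", "clip"):
        raise ValueError("boundary must be 'reflect' or 'clip'")
    rng = np.random.default_rng(seed)

    n_levels = int(np.floor((hi - lo) / step + 1e-9)) + 1
    on_grid = abs((hi - lo) - (n_levels - 1) * step) < 1e-9

    if on_grid:
        # integer-level dynamics keep values exactly on the grid
        levels = np.empty((n_trials, n_arms), dtype=np.int64)
        levels[0] = rng.integers(0, n_levels, size=n_arms)
        for t in range(1, n_trials):
            move = rng.random(n_arms) < hazard
            direction = np.where(rng.random(n_arms) < 0.5, -1, 1)
            nxt = levels[t - 1] + np.where(move, direction, 0)
            if boundary == "reflect":
                bad = (nxt < 0) | (nxt > n_levels - 1)
                nxt = np.where(bad, levels[t - 1] - np.where(move, direction,
                                                             0), nxt)
            nxt = np.clip(nxt, 0, n_levels - 1)
            levels[t] = nxt
        probs = lo + levels * step
    else:
        probs = np.empty((n_trials, n_arms))
        probs[0] = lo + rng.integers(0, n_levels, size=n_arms) * step
        for t in range(1, n_trials):
            move = rng.random(n_arms) < hazard
            direction = np.where(rng.random(n_arms) < 0.5, -step, step)
            delta = np.where(move, direction, 0.0)
            nxt = probs[t - 1] + delta
            if boundary == "reflect":
                bad = (nxt < lo - 1e-12) | (nxt > hi + 1e-12)
                nxt = np.where(bad, probs[t - 1] - delta, nxt)
            probs[t] = np.clip(nxt, lo, hi)
    return RewardWalk(probs=probs, hazard=hazard, step=step, bounds=(lo, hi),
                      seed=seed)


# ---------------------------------------------------------------------------
# Agents
# ---------------------------------------------------------------------------

def simulate_rlck_agent(params: AgentParams, walk: RewardWalk, seed=None,
                        subject_id=None) -> ChoiceData:
    """Simulate an RLCK agent on a walk.

    Choices are sampled from the softmax-over-(Q + CK) policy and rewards
    are Bernoulli(walk.probs[t, choice]); the internal Q/CK updates are the
    exact recursion the likelihood in :mod:`restless.rl_models` evaluates.
    """
    rng = np.random.default_rng(seed)
    T = walk.n_trials
    u_choice = rng.random(T)
    u_reward = rng.random(T)
    choices, rewards = _rlck_sim_core(
        walk.probs, params.alpha, params.beta, params.alpha_ck,
        params.q0, params.ck0, u_choice, u_reward)
    return ChoiceData(choices=choices, rewards=rewards,
                      subject_id=subject_id)


def simulate_hmm_agent(trans_params: TiedHMMParams, walk: RewardWalk,
                       seed=None, subject_id=None):
    """Simulate an agent whose choices come from the tied explore/exploit
    chain: state sampled from the 4-state transition matrix, choices
    deterministic in exploit states and uniform in the explore state.

    Returns ``(ChoiceData, true_states)``; the latent states enable
    decoding-accuracy studies.
    """
    rng = np.random.default_rng(seed)
    trans = build_transition(trans_params)
    n_arms = trans_params.n_arms
    T = walk.n_trials
    states = np.empty(T, dtype=np.int64)
    choices = np.empty(T, dtype=np.int64)
    states[0] = rng.choice(n_arms + 1, p=trans_params.init)
    for t in range(1, T):
        states[t] = rng.choice(n_arms + 1, p=trans[states[t - 1]])
    explore = states == 0
    choices[explore] = rng.integers(0, n_arms, size=int(explore.sum()))
    choices[~explore] = states[~explore] - 1
    rewards = (rng.random(T) < walk.probs[np.arange(T), choices]).astype(float)
    return (ChoiceData(choices=choices, rewards=rewards,
                       subject_id=subject_id), states)


def simulate_shift_agent(p_shift: float, walk: RewardWalk, seed=None,
                         subject_id=None) -> ChoiceData:
    """Outcome-independent agent: shifts to one of the other arms (uniform)
    with probability ``p_shift`` each trial, regardless of reward.  The
    null model for reward-driven shift statistics."""
    if not (0.0 <= p_shift <= 1.0):
        raise ValueError("p_shift must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    T, n_arms = walk.probs.shape
    choices = np.empty(T, dtype=np.int64)
    choices[0] = rng.integers(0, n_arms)
    shift = rng.random(T) < p_shift
    hops = rng.integers(1, n_arms, size=T)
    for t in range(1, T):
        if shift[t]:
            choices[t] = (choices[t - 1] + hops[t]) % n_arms
        else:
            choices[t] = choices[t - 1]
    rewards = (rng.random(T) < walk.probs[np.arange(T), choices]).astype(float)
    return ChoiceData(choices=choices, rewards=rewards,
                      subject_id=subject_id)


# ---------------------------------------------------------------------------
# Questionnaire items and cohorts
# ---------------------------------------------------------------------------

def generate_items(latent_traits, config: CohortConfig,
                   seed=None) -> ItemMatrix:
    """Ordinal item scores from latent subscale traits.

    Each of the 12 items of subscale s for subject i is
    ``round(3.5 + loading * trait_is + noise)`` clamped to 1..6, i.e. a
    coarse graded-response surrogate centered on the scale midpoint.
    """
    traits = np.asarray(latent_traits, dtype=float)
    if traits.ndim != 2 or traits.shape[1] != len(SUBSCALES):
        raise ValueError("latent_traits must be (n_subjects, 3)")
    loadings = np.broadcast_to(np.asarray(config.trait_loadings, dtype=float),
                               (len(SUBSCALES),))
    rng = np.random.default_rng(seed)
    n = traits.shape[0]
    scores = np.empty((n, N_ITEMS), dtype=np.int64)
    for s in range(len(SUBSCALES)):
        cols = slice(s * ITEMS_PER_SUBSCALE, (s + 1) * ITEMS_PER_SUBSCALE)
        noise = rng.normal(0.0, config.item_noise_sd,
                           size=(n, ITEMS_PER_SUBSCALE))
        raw = 3.5 + loadings[s] * traits[:, [s]] + noise
        scores[:, cols] = np.clip(np.rint(raw), 1, 6).astype(np.int64)
    return ItemMatrix(scores=scores)


def _subject_params(z_aloof, config: CohortConfig, rng):
    """Trait-linked RLCK parameters: logit link for the rates, log link for
    beta, each with independent Gaussian noise on the link scale."""
    base = config.base_params
    cpl = config.coupling
    sd = config.param_noise_sd
    n = z_aloof.shape[0]
    alpha = expit(logit(base["alpha"]) + cpl["alpha"] * z_aloof
                  + rng.normal(0, sd["alpha"], n))
    beta = np.exp(np.log(base["beta"]) + cpl["beta"] * z_aloof
                  + rng.normal(0, sd["beta"], n))
    beta = np.clip(beta, 1e-3, 50.0)
    alpha_ck = expit(logit(base["alpha_ck"]) + cpl["alpha_ck"] * z_aloof
                     + rng.normal(0, sd["alpha_ck"], n))
    return alpha, beta, alpha_ck


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort with trait-coupled behavior.

    Latent traits ~ N(0, trait_correlations); the aloof trait drives the
    RLCK parameters through the configured coupling links; each subject
    plays their own freshly generated walk; response times are log-normal
    plus the configured additive offset on shift trials; items come from
    :func:`generate_items`.  Identical config (including seed) yields
    byte-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_subjects

    chol = np.linalg.cholesky(config.trait_correlations)
    traits = rng.standard_normal((n, 3)) @ chol.T
    alpha, beta, alpha_ck = _subject_params(traits[:, 0], config, rng)

    mu, sigma, delta = config.rt_model
    walk_seeds = ss.spawn(n)
    agent_seeds = ss.spawn(n)
    subjects = []
    walks = []
    for i in range(n):
        walk = generate_walk(config.n_trials, config.n_arms, config.hazard,
                             config.step, config.bounds,
                             seed=walk_seeds[i], boundary=config.boundary)
        params = AgentParams(alpha=float(alpha[i]), beta=float(beta[i]),
                             alpha_ck=float(alpha_ck[i]))
        data = simulate_rlck_agent(params, walk, seed=agent_seeds[i],
                                   subject_id=f"s{i:04d}")
        base_rt = rng.lognormal(mu, sigma, config.n_trials)
        shift = np.zeros(config.n_trials, dtype=bool)
        shift[1:] = data.choices[1:] != data.choices[:-1]
        data.rts = base_rt + delta * shift
        subjects.append(data)
        walks.append(walk)

    items = generate_items(traits, config, seed=ss.spawn(1)[0])
    params_df = pd.DataFrame({
        "subject": [d.subject_id for d in subjects],
        "alpha": alpha, "beta": beta, "alpha_ck": alpha_ck,
    })
    return Cohort(subjects=subjects, walks=walks, items=items, traits=traits,
                  params=params_df, config=config)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write a cohort as long-format choices.csv, items.csv, traits.csv and
    a JSON sidecar recording the config and seed.  Returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for d in cohort.subjects:
        for t in range(d.n_trials):
            rows.append((d.subject_id, t, int(d.choices[t]),
                         int(d.rewards[t]),
                         float(d.rts[t]) if d.rts is not None else np.nan))
    choices = pd.DataFrame(rows, columns=["subject", "trial", "choice",
                                          "reward", "rt"])
    choices.to_csv(out / "choices.csv", index=False)

    items = pd.DataFrame(cohort.items.scores,
                         columns=[f"item_{j+1:02d}" for j in range(N_ITEMS)])
    items.insert(0, "subject", [d.subject_id for d in cohort.subjects])
    items.to_csv(out / "items.csv", index=False)

    traits = pd.DataFrame(cohort.traits, columns=list(SUBSCALES))
    traits.insert(0, "subject", [d.subject_id for d in cohort.subjects])
    traits.to_csv(out / "traits.csv", index=False)

    sidecar = {}
    if cohort.config is not None:
        cfg = cohort.config
        sidecar = {
            "seed": cfg.seed,
            "n_subjects": cfg.n_subjects,
            "n_trials": cfg.n_trials,
            "n_arms": cfg.n_arms,
            "hazard": cfg.hazard,
            "step": cfg.step,
            "bounds": list(cfg.bounds),
            "boundary": cfg.boundary,
            "coupling": cfg.coupling,
            "base_params": cfg.base_params,
            "param_noise_sd": cfg.param_noise_sd,
            "rt_model": list(cfg.rt_model),
            "trait_correlations": cfg.trait_correlations.tolist(),
        }
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return {"choices": out / "choices.csv", "items": out / "items.csv",
            "traits": out / "traits.csv", "sidecar": out / "cohort.json"}
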