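"""Model-free behavioral indices of one subject's bandit session.

The nine per-subject features consumed by the sparse-CCA stage are, in
fixed column order: HMM-derived probability of exploration and exploration
potential; punishment sensitivity; shift probability; win-stay; lose-shift;
the shift-minus-stay response-time difference; mean response time; and
reward rate above chance.

Punishment sensitivity measures how much shifting is reward-driven,
normalized by overall shiftiness::

    (P(shift | loss) - P(shift | win)) / P(shift)

All conditioning uses transitions t -> t+1 whose predecessor outcome is
observed (i.e. the last trial never conditions anything).  A metric whose
conditioning set is empty, or whose denominator is zero, is returned as NaN
(a missing flag); downstream correlation analyses exclude missing values
pairwise so that no subject is ever dropped wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "BehavioralProfile",
    "FEATURE_COLUMNS",
    "shift_probability",
    "win_stay",
    "lose_shift",
    "punishment_sensitivity",
    "reward_above_chance",
    "rt_metrics",
    "build_profile",
    "profiles_frame",
]

FEATURE_COLUMNS = (
    "p_explore",
    "exploration_potential",
    "punishment_sensitivity",
    "p_shift",
    "win_stay",
    "lose_shift",
    "rt_shift_minus_stay",
    "rt_mean",
    "reward_above_chance",
)


@dataclass
class BehavioralProfile:
    """The nine-feature behavioral vector for one subject; NaN = missing."""

    p_explore: float
    exploration_potential: float
    punishment_sensitivity: float
    p_shift: float
    win_stay: float
    lose_shift: float
    rt_shift_minus_stay: float
    rt_mean: float
    reward_above_chance: float
    subject_id: str | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "subject_id"}


def _shifts(data):
    """Boolean shift indicator for transitions 1..T-1 (choice_t != choice_{t-1})."""
    c = data.choices
    if c.shape[0] < 2:
        raise ValueError("need at least 2 trials to score transitions")
    return c[1:] != c[:-1]


def shift_probability(data) -> float:
    """Fraction of trials (from the second on) on which the subject chose a
    different arm than on the previous trial."""
    return float(_shifts(data).mean())


def win_stay(data) -> float:
    """P(repeat the choice at t+1 | trial t rewarded); NaN if no rewarded
    trial has a successor."""
    shifts = _shifts(data)
    won = data.rewards[:-1] == 1.0
    if not won.any():
        return np.nan
    return float((~shifts[won]).mean())


def lose_shift(data) -> float:
    """P(switch at t+1 | trial t unrewarded); NaN if no unrewarded trial
    has a successor."""
    shifts = _shifts(data)
    lost = data.rewards[:-1] == 0.0
    if not lost.any():
        return np.nan
    return float(shifts[lost].mean())


def punishment_sensitivity(data) -> float:
    """Relative shift probability after losses versus wins.

    ``(P(shift|loss) - P(shift|win)) / P(shift)`` with all three terms
    computed over the same transition set (trials with a scoreable
    predecessor outcome).  Near zero when shifting is outcome-independent;
    positive when shifts concentrate after losses.  NaN when the subject
    never shifts or one conditioning set is empty.
    """
    shifts = _shifts(data)
    outcome = data.rewards[:-1]
    won = outcome == 1.0
    lost = ~won
    p_shift = shifts.mean()
    if p_shift == 0.0 or not won.any() or not lost.any():
        return np.nan
    return float((shifts[lost].mean() - shifts[won].mean()) / p_shift)


def reward_above_chance(data, walk) -> float:
    """Observed reward rate minus the chance rate of a uniformly random
    chooser (the across-arm mean reward probability, averaged over trials)."""
    if data.n_trials != walk.n_trials:
        raise ValueError(
            f"choice sequence ({data.n_trials} trials) is not aligned to "
            f"the walk ({walk.n_trials} trials)")
    return float(data.rewards.mean() - walk.probs.mean())


def rt_metrics(data) -> tuple[float, float]:
    """(mean RT, mean RT on shift trials minus mean RT on stay trials).

    The difference conditions on transitions 2..T; it is NaN when the
    session has no shift or no stay trials.  Requires RTs.
    """
    if data.rts is None:
        raise ValueError("response times are absent")
    rt_mean = float(data.rts.mean())
    shifts = _shifts(data)
    later = data.rts[1:]
    if shifts.all() or not shifts.any():
        return rt_mean, np.nan
    return rt_mean, float(later[shifts].mean() - later[~shifts].mean())


def build_profile(data, walk=None, hmm_fit=None) -> BehavioralProfile:
    """Assemble the nine-feature vector for one subject.

    ``p_explore`` and ``exploration_potential`` come from the fitted HMM
    (NaN when no fit is supplied); ``reward_above_chance`` needs the walk;
    RT features need response times.  Anything uncomputable is NaN.
    """
    from .explore_hmm import explore_metrics  # local import, no cycle at load

    if hmm_fit is not None:
        em = explore_metrics(hmm_fit)
        p_explore, potential = em.p_explore, em.exploration_potential
    else:
        p_explore, potential = np.nan, np.nan
    if data.rts is not None:
        rt_mean, rt_diff = rt_metrics(data)
    else:
        rt_mean, rt_diff = np.nan, np.nan
    rac = reward_above_chance(data, walk) if walk is not None else np.nan
    return BehavioralProfile(
        p_explore=p_explore,
        exploration_potential=potential,
        punishment_sensitivity=punishment_sensitivity(data),
        p_shift=shift_probability(data),
        win_stay=win_stay(data),
        lose_shift=lose_shift(data),
        rt_shift_minus_stay=rt_diff,
        rt_mean=rt_mean,
        reward_above_chance=rac,
        subject_id=data.subject_id,
    )


def profiles_frame(profiles) -> pd.DataFrame:
    """Stack per-subject profiles into an (n_subjects x 9) feature table
    indexed by subject id, columns in the fixed sCCA order."""
    df = pd.DataFrame([p.as_dict() for p in profiles],
                      index=[p.subject_id for p in profiles])
    df.index.name = "subject"
    return df[list(FEATURE_COLUMNS)]
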