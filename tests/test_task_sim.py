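"""Reward walks, simulated agents and cohort generation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from restless import (
    AgentParams,
    CohortConfig,
    TiedHMMParams,
    build_transition,
    generate_cohort,
    generate_items,
    generate_walk,
    simulate_hmm_agent,
    simulate_rlck_agent,
    simulate_shift_agent,
    win_stay,
)

GRID = np.array([0.1, 0.3, 0.5, 0.7, 0.9])


class TestGenerateWalk:
    def test_default_walk_stays_on_grid(self):
        walk = generate_walk(300, 3, 0.6667, 0.2, (0.1, 0.9), seed=5)
        assert walk.probs.shape == (300, 3)
        assert np.isin(np.round(walk.probs, 12), GRID).all()

    def test_zero_hazard_is_constant(self):
        walk = generate_walk(500, 3, 0.0, 0.2, (0.1, 0.9), seed=1)
        assert (walk.probs == walk.probs[0]).all()

    def test_hazard_one_always_steps(self):
        walk = generate_walk(10_000, 1, 1.0, 0.2, (0.1, 0.9), seed=2)
        p = walk.probs[:, 0]
        assert (p[1:] != p[:-1]).mean() == 1.0

    def test_change_frequency_matches_hazard(self):
        hazard = 0.6667
        walk = generate_walk(100_000, 1, hazard, 0.2, (0.1, 0.9), seed=3)
        p = walk.probs[:, 0]
        changed = (p[1:] != p[:-1]).mean()
        se = np.sqrt(hazard * (1 - hazard) / (len(p) - 1))
        assert abs(changed - hazard) < 3 * se

    def test_bounds_never_violated_long_run(self):
        walk = generate_walk(100_000, 2, 0.9, 0.2, (0.1, 0.9), seed=4)
        assert walk.probs.min() >= 0.1 - 1e-12
        assert walk.probs.max() <= 0.9 + 1e-12
        assert np.isin(np.round(walk.probs, 12), GRID).all()

    def test_clip_boundary_option(self):
        walk = generate_walk(5000, 3, 0.9, 0.2, (0.1, 0.9), seed=6,
                             boundary="clip")
        assert walk.probs.min() >= 0.1 and walk.probs.max() <= 0.9

    @pytest.mark.parametrize("kwargs", [
        {"hazard": -0.1}, {"hazard": 1.5}, {"step": 0.0},
        {"bounds": (0.9, 0.1)}, {"n_trials": 0}, {"boundary": "wrap"},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        base = dict(n_trials=10, n_arms=3, hazard=0.5, step=0.2,
                    bounds=(0.1, 0.9), seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_walk(**base)


class TestRLCKAgent:
    def test_zero_beta_chooses_uniformly(self, default_walk):
        counts = np.zeros(3)
        for s in range(10):
            data = simulate_rlck_agent(AgentParams(0.5, 0.0, 0.3),
                                       default_walk, seed=s)
            counts += np.bincount(data.choices, minlength=3)
        freq = counts / counts.sum()
        se = np.sqrt((1 / 3) * (2 / 3) / counts.sum())
        assert np.abs(freq - 1 / 3).max() < 3 * se

    def test_frozen_values_give_uniform_policy(self, default_walk):
        # alpha = alpha_ck = 0 with equal q0: nothing ever updates
        counts = np.zeros(3)
        for s in range(10):
            data = simulate_rlck_agent(AgentParams(0.0, 8.0, 0.0, q0=0.5),
                                       default_walk, seed=100 + s)
            counts += np.bincount(data.choices, minlength=3)
        freq = counts / counts.sum()
        se = np.sqrt((1 / 3) * (2 / 3) / counts.sum())
        assert np.abs(freq - 1 / 3).max() < 3 * se

    def test_near_greedy_agent_win_stays(self):
        # alpha=1 jumps the rewarded arm's Q to 1; beta=20 makes the
        # softmax effectively greedy, so a win forces a stay
        rates = []
        for s in range(200):
            walk = generate_walk(seed=1000 + s)
            data = simulate_rlck_agent(AgentParams(1.0, 20.0, 0.0), walk,
                                       seed=2000 + s)
            rates.append(win_stay(data))
        assert np.nanmean(rates) > 0.95

    def test_reproducible(self, default_walk):
        a = simulate_rlck_agent(AgentParams(0.4, 5.0, 0.3), default_walk,
                                seed=7)
        b = simulate_rlck_agent(AgentParams(0.4, 5.0, 0.3), default_walk,
                                seed=7)
        assert (a.choices == b.choices).all()
        assert (a.rewards == b.rewards).all()

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            AgentParams(alpha=1.5, beta=1.0)
        with pytest.raises(ValueError):
            AgentParams(alpha=0.5, beta=-1.0)


class TestHMMAgent:
    def test_absorbing_exploit_repeats_one_arm(self, default_walk):
        params = TiedHMMParams(0.0, 0.6, init=[0, 1, 0, 0])
        data, states = simulate_hmm_agent(params, default_walk, seed=1)
        assert (data.choices == data.choices[0]).all()
        assert (states == 1).all()

    def test_absorbing_explore_is_iid_uniform(self, default_walk):
        params = TiedHMMParams(0.05, 0.0, init=[1, 0, 0, 0])
        data, states = simulate_hmm_agent(params, default_walk, seed=2)
        assert (states == 0).all()
        freq = np.bincount(data.choices, minlength=3) / data.n_trials
        se = np.sqrt((1 / 3) * (2 / 3) / data.n_trials)
        assert np.abs(freq - 1 / 3).max() < 4 * se

    def test_stationary_explore_mass_matches_eigen_oracle(self):
        a, b = 0.05, 0.6
        params = TiedHMMParams(a, b)
        walk = generate_walk(n_trials=100_000, seed=3)
        _, states = simulate_hmm_agent(params, walk, seed=4)
        # stationary distribution from the explicit 4x4 matrix
        T = build_transition(params)
        vals, vecs = np.linalg.eig(T.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi /= pi.sum()
        target = pi[0]
        observed = (states == 0).mean()
        se = np.sqrt(target * (1 - target) / len(states))
        # 3 SE with a mixing-time allowance: states are autocorrelated
        assert abs(observed - target) < 8 * se
        assert abs(target - a / (a + b)) < 1e-12

    def test_invalid_transition_probs_raise(self):
        with pytest.raises(ValueError):
            TiedHMMParams(-0.1, 0.5)
        with pytest.raises(ValueError):
            TiedHMMParams(0.5, 1.2)


class TestShiftAgent:
    def test_shift_rate_matches_epsilon(self, default_walk):
        data = simulate_shift_agent(0.3, default_walk, seed=9)
        shifts = (data.choices[1:] != data.choices[:-1]).mean()
        se = np.sqrt(0.3 * 0.7 / (data.n_trials - 1))
        assert abs(shifts - 0.3) < 4 * se


class TestGenerateItems:
    def test_zero_loading_zero_noise_gives_midpoint(self):
        cfg = CohortConfig(n_subjects=5, trait_loadings=0.0,
                           item_noise_sd=0.0)
        traits = np.zeros((5, 3))
        items = generate_items(traits, cfg, seed=0)
        assert (items.scores == 4).all()
        sums = items.subscale_sums()
        assert (sums[["aloof", "rigid", "pragmatic"]] == 48).all().all()

    def test_strong_loading_yields_item_trait_correlation(self):
        from scipy.stats import spearmanr

        cfg = CohortConfig(n_subjects=1000, trait_loadings=2.0,
                           item_noise_sd=0.3)
        rng = np.random.default_rng(5)
        traits = rng.standard_normal((1000, 3))
        items = generate_items(traits, cfg, seed=6)
        rho, _ = spearmanr(items.scores[:, 0], traits[:, 0])
        assert rho > 0.5

    def test_score_ranges(self):
        cfg = CohortConfig(n_subjects=200)
        rng = np.random.default_rng(7)
        items = generate_items(rng.standard_normal((200, 3)), cfg, seed=8)
        sums = items.subscale_sums()
        for sub in ("aloof", "rigid", "pragmatic"):
            assert sums[sub].between(12, 72).all()
        assert sums["total"].between(36, 216).all()


class TestGenerateCohort:
    def test_reproducible_from_config(self):
        cfg = CohortConfig(n_subjects=5, n_trials=50, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(CohortConfig(n_subjects=5, n_trials=50, seed=42))
        for da, db in zip(a.subjects, b.subjects):
            assert (da.choices == db.choices).all()
            assert (da.rewards == db.rewards).all()
            assert np.array_equal(da.rts, db.rts)
        assert (a.items.scores == b.items.scores).all()
        assert np.array_equal(a.traits, b.traits)

    def test_minimal_cohort(self):
        cohort = generate_cohort(CohortConfig(n_subjects=2, n_trials=30,
                                              seed=1))
        assert cohort.n_subjects == 2
        assert cohort.items.scores.shape == (2, 36)
        assert cohort.traits.shape == (2, 3)
        assert len(cohort.walks) == 2

    def test_non_positive_definite_correlation_raises(self):
        bad = np.array([[1.0, 0.99, -0.99],
                        [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=10, trait_correlations=bad)

    def test_zero_coupling_breaks_trait_behavior_link(self):
        # independence by construction: aloof sum should not predict
        # shift rate beyond test-level false positives
        from restless import shift_probability, spearman_with_ci

        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = CohortConfig(
                n_subjects=60, n_trials=80, seed=900 + rep,
                coupling={"alpha": 0.0, "beta": 0.0, "alpha_ck": 0.0})
            cohort = generate_cohort(cfg)
            aloof = cohort.items.subscale_sums()["aloof"].to_numpy()
            p_shift = [shift_probability(d) for d in cohort.subjects]
            rep_ = spearman_with_ci(aloof, np.asarray(p_shift))
            hits += rep_.p_value < 0.05
        # nominal false-positive rate is 5%; 6/50 is the one-sided
        # binomial 97.5% envelope for a calibrated test
        assert hits <= 6


@given(st.integers(0, 2**31 - 1))
def test_walk_entries_always_within_bounds(seed):
    walk = generate_walk(50, 2, 0.8, 0.2, (0.1, 0.9), seed=seed)
    assert walk.probs.min() >= 0.1 - 1e-12
    assert walk.probs.max() <= 0.9 + 1e-12
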