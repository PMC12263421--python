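"""Sparse CCA: soft-thresholding, rank-1 PMD, fitting, tuning, permutation."""

import numpy as np
import pytest
import scipy.linalg as sla

from restless import (
    SCCAInputs,
    permutation_test,
    pmd_rank1,
    scca_fit,
    soft_threshold,
    tune_penalties,
)


def whitened_pair(rng, n=200, p=6, q=4, latent=0.0):
    """Random (B, E) with exact sample-identity within-set covariance."""
    B = rng.standard_normal((n, p))
    E = rng.standard_normal((n, q))
    if latent:
        f = rng.standard_normal(n)
        B[:, 0] += latent * f
        E[:, 0] += latent * f
    B -= B.mean(0)
    E -= E.mean(0)
    B = B @ sla.inv(sla.sqrtm(B.T @ B / (n - 1))).real
    E = E @ sla.inv(sla.sqrtm(E.T @ E / (n - 1))).real
    return B, E


def classical_cca_first_corr(Bs, Es):
    """Eigen-decomposition oracle for the first canonical correlation."""
    n = Bs.shape[0]
    Sbb = Bs.T @ Bs / (n - 1)
    See = Es.T @ Es / (n - 1)
    Sbe = Bs.T @ Es / (n - 1)
    M = sla.solve(Sbb, Sbe) @ sla.solve(See, Sbe.T)
    return float(np.sqrt(np.max(np.linalg.eigvals(M).real)))


class TestSoftThreshold:
    @pytest.mark.parametrize("a,lam,expected", [
        (2.0, 0.5, 1.5),
        (-0.3, 0.5, 0.0),
        (-2.0, 1.0, -1.0),
    ])
    def test_scalar_examples(self, a, lam, expected):
        assert soft_threshold(a, lam) == pytest.approx(expected)

    def test_elementwise_on_vectors(self):
        out = soft_threshold(np.array([2.0, -0.3, -2.0]), 0.5)
        assert np.allclose(out, [1.5, 0.0, -1.5])

    def test_negative_threshold_raises(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestPMDRank1:
    def test_c1_equals_one_gives_one_hot(self, rng):
        Z = rng.standard_normal((8, 5))
        x, y, d = pmd_rank1(Z, 1.0, np.sqrt(5))
        nz = np.abs(x) > 1e-9
        assert nz.sum() == 1
        assert abs(np.abs(x).max() - 1.0) < 1e-9

    def test_objective_monotone(self, rng):
        for _ in range(10):
            Z = rng.standard_normal((10, 6))
            _, _, _, trace = pmd_rank1(Z, 2.0, 1.8, return_trace=True)
            assert (np.diff(trace) >= -1e-12).all()

    def test_norm_constraints_hold(self, rng):
        for _ in range(10):
            p, q = 12, 7
            Z = rng.standard_normal((p, q))
            c1 = rng.uniform(1, np.sqrt(p))
            c2 = rng.uniform(1, np.sqrt(q))
            x, y, _ = pmd_rank1(Z, c1, c2)
            assert np.linalg.norm(x) <= 1 + 1e-8
            assert np.linalg.norm(y) <= 1 + 1e-8
            assert np.abs(x).sum() <= c1 + 1e-6
            assert np.abs(y).sum() <= c2 + 1e-6

    def test_zero_matrix_degenerate_flag(self):
        x, y, d = pmd_rank1(np.zeros((4, 3)), 1.5, 1.5)
        assert x is None and y is None and d == 0.0

    def test_out_of_range_penalty_raises(self):
        Z = np.ones((4, 3))
        with pytest.raises(ValueError):
            pmd_rank1(Z, 0.5, 1.5)
        with pytest.raises(ValueError):
            pmd_rank1(Z, 1.5, 5.0)

    def test_unpenalized_limit_matches_classical_cca(self):
        rng = np.random.default_rng(2024)
        for i in range(20):
            B, E = whitened_pair(rng, latent=0.5 if i % 2 else 0.0)
            inp = SCCAInputs(B, E)
            fit = scca_fit(inp, 1.0, 1.0, n_components=1)
            cc = fit.components[0].canonical_correlation
            Bs, Es = inp.standardized()
            assert abs(cc - classical_cca_first_corr(Bs, Es)) < 1e-3

    def test_deflation_d_non_increasing_unpenalized(self, rng):
        B, E = whitened_pair(np.random.default_rng(7), n=300, p=6, q=5)
        fit = scca_fit(SCCAInputs(B, E), 1.0, 1.0, n_components=4)
        ds = [c.d for c in fit.components]
        assert all(ds[i] >= ds[i + 1] - 1e-9 for i in range(len(ds) - 1))


class TestSCCAFit:
    def test_penalty_mapping_example(self, rng):
        B = rng.standard_normal((50, 36))
        E = rng.standard_normal((50, 9))
        fit = scca_fit(SCCAInputs(B, E), 1.0, 0.9, n_components=1)
        assert fit.c1 == pytest.approx(6.0)
        assert fit.c2 == pytest.approx(2.7)

    def test_self_correlation_is_one(self, rng):
        B = rng.standard_normal((80, 5))
        fit = scca_fit(SCCAInputs(B, B.copy()), 1.0, 1.0, n_components=1)
        assert fit.components[0].canonical_correlation == pytest.approx(
            1.0, abs=1e-8)

    def test_planted_factor_recovery(self):
        rng = np.random.default_rng(11)
        n = 1000
        f = rng.standard_normal(n)
        B = rng.standard_normal((n, 36))
        E = rng.standard_normal((n, 9))
        planted = [0, 5, 11, 20]
        for j in planted:
            B[:, j] += 1.0 * f
        E[:, 0] += 1.0 * f
        fit = scca_fit(SCCAInputs(B, E), 1.0, 0.9, n_components=1)
        x = fit.components[0].x
        top4 = set(np.argsort(np.abs(x))[-4:])
        assert top4 == set(planted)
        # sign convention: dominant-loading item weight is positive
        assert x[np.argmax(np.abs(fit.components[0].b_loadings))] > 0

    def test_constant_column_error_names_column(self, rng):
        B = rng.standard_normal((30, 4))
        B[:, 2] = 1.0
        E = rng.standard_normal((30, 3))
        with pytest.raises(ValueError, match="b2"):
            SCCAInputs(B, E)

    def test_invalid_scales_raise(self, rng):
        inp = SCCAInputs(rng.standard_normal((30, 4)),
                         rng.standard_normal((30, 3)))
        with pytest.raises(ValueError):
            scca_fit(inp, 0.0, 0.5)
        with pytest.raises(ValueError):
            scca_fit(inp, 0.5, 1.2)


class TestTunePenalties:
    def test_deterministic_given_seed(self, rng):
        B = rng.standard_normal((120, 8))
        E = rng.standard_normal((120, 4))
        inp = SCCAInputs(B, E)
        grid = [0.4, 0.7, 1.0]
        out1 = tune_penalties(inp, grid=grid, k_folds=4, n_resamples=2,
                              seed=5)
        out2 = tune_penalties(inp, grid=grid, k_folds=4, n_resamples=2,
                              seed=5)
        assert out1[:2] == out2[:2]
        assert np.allclose(out1[2]["cv_score"], out2[2]["cv_score"])

    def test_pure_noise_has_no_held_out_signal(self):
        rng = np.random.default_rng(21)
        B = rng.standard_normal((500, 12))
        E = rng.standard_normal((500, 5))
        s1, s2, table = tune_penalties(SCCAInputs(B, E),
                                       grid=[0.3, 0.65, 1.0], k_folds=5,
                                       n_resamples=3, seed=0)
        sel = table[(table.c1_scale == s1) & (table.c2_scale == s2)]
        assert float(sel["cv_score"].iloc[0]) < 0.2

    def test_sparsity_helps_on_planted_sparse_signal(self):
        picks = []
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = 240
            f = rng.standard_normal(n)
            B = rng.standard_normal((n, 36))
            E = rng.standard_normal((n, 9))
            for j in (0, 9, 18, 27):
                B[:, j] += 1.2 * f
            E[:, 0] += 1.2 * f
            s1, _, _ = tune_penalties(SCCAInputs(B, E),
                                      grid=[0.3, 0.65, 1.0], k_folds=4,
                                      n_resamples=2, seed=rep)
            picks.append(s1 < 1.0)
        assert np.mean(picks) >= 0.6

    def test_tiny_folds_raise(self, rng):
        inp = SCCAInputs(rng.standard_normal((15, 4)),
                         rng.standard_normal((15, 3)))
        with pytest.raises(ValueError):
            tune_penalties(inp, k_folds=10, n_resamples=1)


class TestPermutationTest:
    def test_planted_signal_is_significant(self):
        rng = np.random.default_rng(31)
        n = 600
        f = rng.standard_normal(n)
        B = rng.standard_normal((n, 12))
        E = rng.standard_normal((n, 5))
        B[:, 0] += 0.8 * f
        E[:, 0] += 0.8 * f
        inp = SCCAInputs(B, E)
        fit = scca_fit(inp, 1.0, 0.9, n_components=1)
        p, p_fdr = permutation_test(inp, fit, n_perm=200, seed=0)
        assert p[0] < 0.05
        assert p[0] >= 1.0 / 201.0          # estimator floor
        assert p_fdr[0] >= p[0]

    def test_few_permutations_sets_warning(self, rng):
        B = rng.standard_normal((40, 5))
        E = rng.standard_normal((40, 4))
        inp = SCCAInputs(B, E)
        fit = scca_fit(inp, 1.0, 1.0, n_components=1)
        permutation_test(inp, fit, n_perm=50, seed=1)
        assert fit.perm_warning is not None
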