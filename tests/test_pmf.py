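"""Uncertainty model and weighted nonnegative factorization engine."""

import numpy as np
import pandas as pd
import pytest

from soilpte import pmf
from soilpte.synthetic import generate_survey


def random_positive_problem(rng, n=25, m=6, k=3, noise=0.1):
    """Random low-rank positive matrix with proportional uncertainties."""
    G = rng.gamma(2.0, 1.0, size=(n, k))
    F = rng.gamma(2.0, 1.0, size=(k, m)) + 0.1
    X = G @ F
    X *= rng.lognormal(0.0, noise, size=X.shape)
    U = 0.1 * X + 0.05
    return X, U, G, F


def weighted_rank1_als(X, U, iters=2000, seed=0):
    """Independent oracle: alternating weighted least squares, rank 1."""
    rng = np.random.default_rng(seed)
    W = 1.0 / U**2
    g = rng.uniform(0.5, 1.5, size=X.shape[0])
    f = X.mean(axis=0)
    for _ in range(iters):
        g = np.clip((W * X * f).sum(axis=1) / (W * f**2).sum(axis=1), 0, None)
        f = np.clip((W * X * g[:, None]).sum(axis=0)
                    / (W * g[:, None] ** 2).sum(axis=0), 0, None)
    return g, f


class TestUncertaintyMatrix:
    def test_censored_branch(self):
        X = pd.DataFrame({"Hg": [4e-4, 0.03]})
        um = pmf.uncertainty_matrix(X, {"Hg": 5e-4}, {"Hg": 0.1}, weak_sn=None)
        assert um.below_mdl[0, 0] and not um.below_mdl[1, 0]
        assert um.u[0, 0] == pytest.approx(5 / 6 * 5e-4)

    def test_value_at_mdl_uses_censored_branch(self):
        X = pd.DataFrame({"Hg": [5e-4, 0.03]})
        um = pmf.uncertainty_matrix(X, {"Hg": 5e-4}, {"Hg": 0.1}, weak_sn=None)
        assert um.below_mdl[0, 0]

    def test_above_mdl_product_form(self):
        X = pd.DataFrame({"As": [10.0]})
        um = pmf.uncertainty_matrix(X, {"As": 0.6}, {"As": 0.1}, weak_sn=None)
        assert um.u[0, 0] == pytest.approx(np.hypot(0.1 * 10.0, 0.3))

    def test_asymptotically_relative(self):
        X = pd.DataFrame({"As": [1e6]})
        um = pmf.uncertainty_matrix(X, {"As": 0.6}, {"As": 0.1}, weak_sn=None)
        assert um.u[0, 0] == pytest.approx(0.1 * 1e6, rel=1e-6)

    def test_nonpositive_mdl_rejected(self):
        with pytest.raises(ValueError):
            pmf.uncertainty_matrix(pd.DataFrame({"As": [1.0]}), {"As": 0.0})

    def test_weak_element_uncertainty_tripled(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"A": rng.uniform(10, 20, 50),
                          "B": rng.uniform(0.01, 0.02, 50)})
        with pytest.warns(UserWarning, match="weak"):
            um = pmf.uncertainty_matrix(X, {"A": 0.1, "B": 1.0}, 0.1)
        plain = pmf.uncertainty_matrix(X, {"A": 0.1, "B": 1.0}, 0.1, weak_sn=None)
        np.testing.assert_allclose(um.u[:, 1], 3 * plain.u[:, 1])
        np.testing.assert_allclose(um.u[:, 0], plain.u[:, 0])


class TestQValue:
    def test_exact_factorization_zero(self):
        rng = np.random.default_rng(0)
        _, _, G, F = random_positive_problem(rng)
        X = G @ F
        assert pmf.q_value(X, np.ones_like(X), G, F) == pytest.approx(0.0, abs=1e-18)

    def test_single_cell_hand_value(self):
        # x=3, model=1, u=2 -> ((3-1)/2)^2 = 1
        assert pmf.q_value(np.array([[3.0]]), np.array([[2.0]]),
                           np.array([[1.0]]), np.array([[1.0]])) == pytest.approx(1.0)

    def test_robust_never_exceeds_true(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X, U, G, F = random_positive_problem(rng, noise=0.5)
            Gr = G * rng.lognormal(0, 0.3, G.shape)
            assert pmf.q_value(X, U, Gr, F, robust=True) <= pmf.q_value(X, U, Gr, F)

    def test_zero_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            pmf.q_value(np.ones((2, 2)), np.zeros((2, 2)),
                        np.ones((2, 1)), np.ones((1, 2)))


class TestFit:
    def test_noiseless_exact_rank(self):
        rng = np.random.default_rng(2)
        _, _, G, F = random_positive_problem(rng, n=40, m=7, k=3)
        X = G @ F
        U = 0.1 * X + 0.01
        sol = pmf.fit_pmf(X, U, 3, n_starts=5, seed=0)
        dof = X.size - 3 * (X.shape[0] + X.shape[1])
        assert sol.q_true / max(dof, 1) < 1e-4

    def test_q_monotone_within_run(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X, U, _, _ = random_positive_problem(rng)
            sol = pmf.fit_pmf(X, U, 2, n_starts=1, seed=int(rng.integers(1e6)),
                              max_iter=300)
            q = sol.q_history
            assert (np.diff(q) <= q[:-1] * 1e-12 + 1e-9).all()

    def test_rank1_matches_als_oracle(self):
        rng = np.random.default_rng(4)
        G = rng.gamma(2.0, 1.0, size=(30, 1))
        F = rng.gamma(2.0, 1.0, size=(1, 6)) + 0.2
        X = G @ F * rng.lognormal(0, 0.05, size=(30, 6))
        U = 0.1 * X + 0.02
        sol = pmf.fit_pmf(X, U, 1, n_starts=3, seed=0)
        g_o, f_o = weighted_rank1_als(X, U)
        q_sol = sol.q_true
        q_oracle = pmf.q_value(X, U, g_o[:, None], f_o[None, :])
        assert q_sol == pytest.approx(q_oracle, rel=1e-4)
        # profiles agree up to scale
        ratio = sol.f.ravel() / f_o
        np.testing.assert_allclose(ratio / ratio.mean(), 1.0, rtol=1e-3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X, U, _, _ = random_positive_problem(rng)
        s1 = pmf.fit_pmf(X, U, 2, n_starts=3, seed=11, max_iter=500)
        s2 = pmf.fit_pmf(X, U, 2, n_starts=3, seed=11, max_iter=500)
        np.testing.assert_array_equal(s1.g, s2.g)
        np.testing.assert_array_equal(s1.f, s2.f)

    def test_nonnegativity_and_normalization(self):
        rng = np.random.default_rng(6)
        X, U, _, _ = random_positive_problem(rng)
        sol = pmf.fit_pmf(X, U, 3, n_starts=2, seed=0, max_iter=500)
        assert (sol.g >= 0).all() and (sol.f >= 0).all()
        np.testing.assert_allclose(sol.g.mean(axis=0), 1.0, rtol=1e-12)

    def test_invalid_factor_count(self):
        X = np.ones((4, 3)) + np.eye(4, 3)
        with pytest.raises(ValueError):
            pmf.fit_pmf(X, np.ones_like(X), 5, n_starts=1, seed=0)


class TestScan:
    def test_q_expected_arithmetic(self):
        rng = np.random.default_rng(7)
        X, U, _, _ = random_positive_problem(rng, n=30, m=8, k=2)
        scan = pmf.scan_factors(X, U, 2, 4, n_starts=2, seed=0, max_iter=300)
        row = scan[scan["n_factors"] == 4].iloc[0]
        assert row["q_expected"] == 30 * 8 - 4 * (30 + 8)

    def test_q_robust_non_increasing_in_p(self):
        rng = np.random.default_rng(8)
        X, U, _, _ = random_positive_problem(rng, n=40, m=8, k=3, noise=0.2)
        scan = pmf.scan_factors(X, U, 1, 5, n_starts=4, seed=3, max_iter=800)
        q = scan["q_robust"].to_numpy()
        assert (np.diff(q) <= 0.05 * q[:-1]).all(), "allow small multi-start noise"

    def test_p_max_bound(self):
        X = np.ones((6, 5)) + np.eye(6, 5)
        with pytest.raises(ValueError):
            pmf.scan_factors(X, np.ones_like(X), 2, 5, n_starts=1, seed=0)


class TestContributionTable:
    def _solution(self, g, f, elements=()):
        return pmf.PMFSolution(g=g, f=f, q_true=0.0, q_robust=0.0,
                               q_expected=1.0, n_starts=1, best_start_seed=0,
                               converged=True, iterations=1,
                               q_history=np.zeros(1), elements=tuple(elements))

    def test_single_factor_everything(self):
        sol = self._solution(np.ones((5, 1)), np.array([[2.0, 3.0]]))
        tab = pmf.contribution_table(sol)
        np.testing.assert_allclose(tab.pct.to_numpy(), 100.0)
        assert tab.share.iloc[0] == pytest.approx(100.0)

    def test_disjoint_support_block_pattern(self):
        f = np.array([[4.0, 0.0], [0.0, 6.0]])
        sol = self._solution(np.ones((5, 2)), f)
        tab = pmf.contribution_table(sol)
        np.testing.assert_allclose(tab.pct.to_numpy(), [[100, 0], [0, 100]])
        np.testing.assert_allclose(tab.share.to_numpy(), [40.0, 60.0])

    def test_scale_indeterminacy_invariant(self):
        rng = np.random.default_rng(9)
        g = rng.gamma(2, 1, (20, 3))
        f = rng.gamma(2, 1, (3, 5))
        base = pmf.contribution_table(self._solution(g, f))
        alpha = np.array([0.5, 2.0, 7.0])
        rescaled = pmf.contribution_table(self._solution(g / alpha, f * alpha[:, None]))
        np.testing.assert_allclose(base.pct, rescaled.pct, rtol=1e-10)
        np.testing.assert_allclose(base.share, rescaled.share, rtol=1e-10)

    def test_columns_sum_to_100(self, survey304, scenario):
        table, _ = survey304
        um = pmf.uncertainty_matrix(table, scenario.mdl, 0.05)
        sol = pmf.fit_pmf(table.conc, um.u, 4, n_starts=2, seed=0,
                          max_iter=800, elements=table.elements)
        tab = pmf.contribution_table(sol, force=True)
        np.testing.assert_allclose(tab.pct.sum(axis=0), 100.0, atol=1e-6)
        assert tab.share.sum() == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_factor_rejected(self):
        sol = self._solution(np.ones((4, 2)), np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="zero"):
            pmf.contribution_table(sol)


class TestAlignment:
    def test_self_alignment_identity(self):
        f = np.random.default_rng(10).gamma(2, 1, (4, 8))
        perm, sims = pmf.align_factors(f, f)
        np.testing.assert_array_equal(perm, np.arange(4))
        np.testing.assert_allclose(sims, 1.0)

    def test_permutation_recovered(self):
        f = np.random.default_rng(11).gamma(2, 1, (4, 8))
        order = np.array([2, 0, 3, 1])
        perm, sims = pmf.align_factors(f[order], f)
        np.testing.assert_array_equal(perm, order)
        np.testing.assert_allclose(sims, 1.0)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pmf.align_factors(np.ones((3, 5)), np.ones((4, 5)))

    def test_similarity_decreases_with_noise(self):
        rng = np.random.default_rng(12)
        f = rng.gamma(2, 1, (4, 8))
        sims_by_noise = []
        for noise in (0.01, 0.3, 1.0):
            sims = []
            for _ in range(20):
                fn = np.clip(f + noise * rng.standard_normal(f.shape), 0, None)
                _, s = pmf.align_factors(fn, f)
                sims.append(s.mean())
            sims_by_noise.append(np.mean(sims))
        assert sims_by_noise[0] > sims_by_noise[1] > sims_by_noise[2]


class TestSignalToNoise:
    def test_signal_free_is_zero(self):
        X = np.full((10, 2), 0.5)
        U = np.ones((10, 2))
        np.testing.assert_allclose(pmf.signal_to_noise(X, U), 0.0)

    def test_strong_signal_scales(self):
        X = np.full((10, 1), 9.0)
        U = np.ones((10, 1))
        assert pmf.signal_to_noise(X, U)[0] == pytest.approx(8.0)
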