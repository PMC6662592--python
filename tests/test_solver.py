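import numpy as np
import pytest

from wfpgl.core import (
    PathwayCollection,
    PenaltyConfig,
    SampleCovariance,
    build_support_mask,
    build_weight_matrix,
    compute_sample_covariance,
)
from wfpgl.pathways import build_block_views, normalize_pathways
from wfpgl.solver import (
    ADMMState,
    fit_wfpgl,
    has_converged,
    sweep_theta,
    update_theta_block,
    update_v,
    update_z,
)

from ._oracles import numeric_theta_minimum, theta_block_objective


class TestThetaBlockUpdate:
    def test_identity_covariance_scalar_solution(self):
        # stationarity −1/t + 1 + t = 0 per eigenvalue gives t = (−1+√5)/2
        T = update_theta_block(
            np.eye(2), np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)), 1, 1.0
        )
        np.testing.assert_allclose(T, ((-1 + np.sqrt(5)) / 2) * np.eye(2), atol=1e-12)

    def test_unpenalized_limit_recovers_inverse_covariance(self, rng):
        p = 4
        A = rng.normal(0, 1, (p, p))
        S = A @ A.T / p + np.eye(p)
        Z = np.zeros((p, p))
        T = update_theta_block(S, Z, Z, Z, n_k=10**9, mu=1.0)
        np.testing.assert_allclose(T, np.linalg.inv(S), atol=1e-6)

    def test_result_minus_delta_is_pd(self, rng):
        for _ in range(20):
            p = int(rng.integers(1, 5))
            A = rng.normal(0, 1, (p, p))
            S = (A + A.T) / 2 + p * np.eye(p)
            B = rng.normal(0, 0.3, (p, p))
            Delta = 0.1 * B @ B.T
            Zs = rng.normal(0, 0.2, (p, p))
            Zs = (Zs + Zs.T) / 2
            T = update_theta_block(S, Delta, Zs, np.zeros((p, p)), 5, 0.7)
            assert np.linalg.eigvalsh(T - Delta).min() > 0

    def test_non_symmetric_input_rejected(self):
        S = np.array([[1.0, 0.5], [0.0, 1.0]])
        Z = np.zeros((2, 2))
        with pytest.raises(ValueError, match="symmetric"):
            update_theta_block(S, Z, Z, Z, 1, 1.0)

    def test_matches_numeric_minimizer(self, rng):
        # closed form attains the numeric minimum of the block objective
        for _ in range(15):
            p = int(rng.integers(1, 4))
            A = rng.normal(0, 1, (p, p))
            S = (A + A.T) / 2 + p * np.eye(p)
            B = rng.normal(0, 0.3, (p, p))
            Delta = 0.1 * B @ B.T
            Zs = rng.normal(0, 0.2, (p, p))
            Zs = (Zs + Zs.T) / 2
            V = rng.normal(0, 0.1, (p, p))
            V = (V + V.T) / 2
            n_k = int(rng.integers(1, 100))
            mu = float(rng.uniform(0.3, 2.0))
            Theta = update_theta_block(S, Delta, Zs, V, n_k, mu)
            f_closed = theta_block_objective(Theta - Delta, S, Delta, Zs, V, n_k, mu)
            f_num = numeric_theta_minimum(S, Delta, Zs, V, n_k, mu, x_init=Theta - Delta)
            assert f_closed <= f_num + 1e-7


class TestSweepTheta:
    def _toy(self, rng, pathway_sets, p, n=50):
        pc = normalize_pathways(PathwayCollection(pathways=pathway_sets), p)
        Q = build_support_mask(pc, p)
        views = build_block_views(pc, Q)
        X = rng.normal(0, 1, (p, n))
        S = SampleCovariance([compute_sample_covariance(X)])
        return pc, Q, views, S, [n]

    def test_single_pathway_equals_global_update(self, rng):
        p = 5
        pc, Q, views, S, n = self._toy(rng, [list(range(p))], p)
        cfg = PenaltyConfig()
        st = ADMMState(Theta=[np.eye(p)], Z=[np.zeros((p, p))], V=[np.zeros((p, p))])
        sweep_theta(st, S, n, views, cfg)
        expect = update_theta_block(
            S[0], np.zeros((p, p)), np.zeros((p, p)), np.zeros((p, p)), n[0], cfg.mu
        )
        np.testing.assert_allclose(st.Theta[0], expect, atol=1e-12)

    def test_disjoint_blocks_order_invariant(self, rng):
        p = 6
        pc, Q, views, S, n = self._toy(rng, [[0, 1, 2], [3, 4, 5]], p)
        cfg = PenaltyConfig()
        st1 = ADMMState(Theta=[np.eye(p)], Z=[np.zeros((p, p))], V=[np.zeros((p, p))])
        st2 = ADMMState(Theta=[np.eye(p)], Z=[np.zeros((p, p))], V=[np.zeros((p, p))])
        sweep_theta(st1, S, n, views, cfg)
        sweep_theta(st2, S, n, list(reversed(views)), cfg)
        np.testing.assert_allclose(st1.Theta[0], st2.Theta[0], atol=1e-12)

    def test_sweep_does_not_increase_augmented_lagrangian(self, rng):
        p = 3
        pc, Q, views, S, n = self._toy(rng, [[0, 1], [1, 2]], p)
        cfg = PenaltyConfig(lambda1=0.1, lambda2=0.0)
        Z0 = rng.normal(0, 0.05, (p, p))
        Z0 = (Z0 + Z0.T) / 2
        st = ADMMState(Theta=[np.eye(p)], Z=[Z0], V=[np.zeros((p, p))])

        def auglag(Theta):
            sign, ld = np.linalg.slogdet(Theta)
            val = -n[0] * (ld - np.trace(S[0] @ Theta))
            val += cfg.mu / 2 * np.sum((Theta - st.Z[0] + st.V[0]) ** 2)
            return val - cfg.mu / 2 * np.sum(st.V[0] ** 2)

        before = auglag(st.Theta[0])
        sweep_theta(st, S, n, views, cfg)
        assert auglag(st.Theta[0]) <= before + 1e-10

    def test_entries_outside_mask_stay_zero(self, rng):
        p = 6
        pc, Q, views, S, n = self._toy(rng, [[0, 1, 2], [2, 3], [3, 4, 5]], p)
        st = ADMMState(Theta=[np.eye(p)], Z=[np.zeros((p, p))], V=[np.zeros((p, p))])
        for _ in range(3):
            sweep_theta(st, S, n, views, PenaltyConfig())
        assert not st.Theta[0][~Q.Q.astype(bool)].any()


class TestDualAndConvergence:
    def test_dual_update_rules(self, rng):
        p = 3
        V = [rng.normal(0, 1, (p, p))]
        T = [rng.normal(0, 1, (p, p))]
        np.testing.assert_allclose(update_v(V, T, T)[0], V[0], atol=1e-14)
        E = T[0] - V[0]
        assert np.allclose(update_v([np.zeros((p, p))], T, V)[0], E)
        twice = update_v(update_v(V, T, [np.zeros((p, p))]), T, [np.zeros((p, p))])
        np.testing.assert_allclose(twice[0], V[0] + 2 * T[0], atol=1e-14)

    def test_identical_iterates_converged(self):
        T = [np.eye(3)]
        assert has_converged(T, T, 1e-5)

    def test_known_ratio_not_converged(self):
        # ‖0.1·I‖²/‖I‖² = 0.01 for any p
        prev = [np.eye(10)]
        curr = [1.1 * np.eye(10)]
        assert not has_converged(prev, curr, 1e-5)
        assert has_converged(prev, curr, 0.02)

    def test_infinite_tolerance_always_converged(self, rng):
        prev = [rng.normal(0, 1, (4, 4))]
        curr = [rng.normal(0, 1, (4, 4))]
        assert has_converged(prev, curr, np.inf)

    def test_zero_previous_iterate_rejected(self):
        with pytest.raises(ZeroDivisionError):
            has_converged([np.zeros((2, 2))], [np.eye(2)], 1e-5)


class TestFitLimits:
    def test_huge_lambda1_gives_diagonal_networks(self, small_scenario):
        sc = small_scenario
        fit = fit_wfpgl(
            sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, None,
            PenaltyConfig(lambda1=1e6, lambda2=0.0),
        )
        for Z in fit.networks:
            off = Z[~np.eye(Z.shape[0], dtype=bool)]
            assert np.all(off == 0.0)

    def test_huge_lambda2_ties_all_states(self, small_scenario):
        sc = small_scenario
        fit = fit_wfpgl(
            sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, None,
            PenaltyConfig(lambda1=0.2, lambda2=1e6),
        )
        np.testing.assert_array_equal(fit.networks[0], fit.networks[1])

    def test_zero_prior_weight_edges_never_shrunk(self, small_scenario):
        sc = small_scenario
        W0 = build_weight_matrix(sc["truth"].G, 0.0)
        fit = fit_wfpgl(
            sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, W0,
            PenaltyConfig(lambda1=1e6, lambda2=0.0),
        )
        # prior edges survive even under a crushing sparsity penalty
        G = sc["truth"].G.G.astype(bool)
        for Z, T in zip(fit.networks, fit.precisions):
            np.testing.assert_array_equal(Z[G], T[G])
            assert np.abs(Z[G]).max() > 0


class TestFitInvariants:
    def test_iterates_pd_and_supported(self, small_scenario):
        sc = small_scenario
        fit = fit_wfpgl(
            sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, sc["W"],
            PenaltyConfig(lambda1=0.2, lambda2=0.01),
        )
        assert fit.converged and fit.n_iter <= 500
        Qb = sc["truth"].Q.Q.astype(bool)
        for T in fit.precisions:
            np.linalg.cholesky(T)  # PD
            assert not T[~Qb].any()
        for Z in fit.networks:
            assert not Z[~Qb].any()

    def test_fixed_point_gap_small_at_tight_tolerance(self, small_scenario):
        sc = small_scenario
        fit = fit_wfpgl(
            sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, sc["W"],
            PenaltyConfig(lambda1=0.2, lambda2=0.01, tol=1e-11, max_iter=3000),
        )
        assert fit.converged
        gap = max(np.abs(T - Z).max() for T, Z in zip(fit.precisions, fit.networks))
        assert gap < 1e-3

    def test_gene_permutation_equivariance(self, small_scenario):
        sc = small_scenario
        rng = np.random.default_rng(0)
        p = sc["cfg"].p
        perm = rng.permutation(p)
        cfg = PenaltyConfig(lambda1=0.2, lambda2=0.01)
        fit = fit_wfpgl(
            sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, sc["W"], cfg
        )
        S_p = [Sk[np.ix_(perm, perm)] for Sk in sc["S"]]
        inv = np.empty(p, dtype=int)
        inv[perm] = np.arange(p)
        pw_p = PathwayCollection(
            pathways=[[int(inv[i]) for i in P] for P in sc["truth"].pathways]
        )
        from wfpgl.core import PriorNetwork

        W_p = build_weight_matrix(
            PriorNetwork(G=sc["truth"].G.G[np.ix_(perm, perm)]), 0.3
        )
        fit_p = fit_wfpgl(S_p, sc["data"].sample_sizes, pw_p, W_p, cfg)
        for Z, Zp in zip(fit.networks, fit_p.networks):
            np.testing.assert_allclose(Zp, Z[np.ix_(perm, perm)], atol=1e-8)

    def test_sparsity_monotone_in_lambda1(self, small_scenario):
        sc = small_scenario
        nnz = []
        for lam1 in (0.5, 2.0, 8.0, 32.0):
            fit = fit_wfpgl(
                sc["S"], sc["data"].sample_sizes, sc["truth"].pathways, None,
                PenaltyConfig(lambda1=lam1, lambda2=0.01),
            )
            nnz.append(sum(int((np.triu(Z, 1) != 0).sum()) for Z in fit.networks))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_graphical_lasso_reduction(self, rng):
        # K=1, all-covering pathway, no prior: matches sklearn's glasso
        import warnings

        from sklearn.covariance import graphical_lasso

        p, n = 20, 200
        A = rng.normal(0, 1, (p, p))
        Prec = A @ A.T / p + 0.5 * np.eye(p)
        X = np.linalg.cholesky(np.linalg.inv(Prec)) @ rng.standard_normal((p, n))
        S = compute_sample_covariance(X)
        lam1 = 20.0
        fit = fit_wfpgl(
            [S], [n], PathwayCollection(pathways=[list(range(p))]), None,
            PenaltyConfig(lambda1=lam1, lambda2=0.0, tol=1e-12, max_iter=5000),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, prec_skl = graphical_lasso(S, alpha=lam1 / n, tol=1e-12, max_iter=10000)
        assert np.abs(fit.networks[0] - prec_skl).max() < 1e-3
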