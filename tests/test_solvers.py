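"""Greedy solver machinery: scores, deflation, schedule, residual updates,
and full solver behavior on constructed instances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fmtrecon as fr
from fmtrecon.mesh import complete_graph
from fmtrecon.solvers import (
    DegenerateCandidatesError,
    GreedyState,
    q_vector,
    _select_one,
)
from conftest import connected_sparse_signal


def path_graph(n):
    return fr.NeighborGraph(
        adjacency=[frozenset(x for x in (k - 1, k + 1) if 0 <= x < n)
                   for k in range(n)])


class TestOlsScores:
    def test_identity_columns_reduce_to_correlation(self):
        A = np.eye(3)
        st_ = GreedyState.fresh(A, np.array([0.0, 5.0, 0.0]))
        scores = fr.ols_scores(A, st_, np.arange(3))
        assert int(np.argmax(scores)) == 1

    def test_hand_evaluated_two_columns(self):
        A = np.array([[1.0, 0.6], [0.0, 0.8]])
        st_ = GreedyState.fresh(A, np.array([1.0, 0.0]))
        scores = fr.ols_scores(A, st_, np.arange(2))
        assert scores == pytest.approx([1.0, 0.6])

    def test_zero_residual_zero_scores(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 8))
        st_ = GreedyState.fresh(A, np.zeros(5))
        assert np.allclose(fr.ols_scores(A, st_, np.arange(8)), 0.0)

    def test_exhausted_candidates_raise(self):
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        st_ = GreedyState.fresh(A, np.array([1.0, 0.0]))
        st_.T[:] = 0.0  # all deflated directions gone
        with pytest.raises(DegenerateCandidatesError):
            fr.ols_scores(A, st_, np.arange(2))


class TestDeflation:
    def test_parallel_column_vanishes(self):
        A = np.array([[1.0, 2.0], [0.0, 0.0]])
        st_ = GreedyState.fresh(A, np.array([1.0, 0.0]))
        fr.deflate_columns(st_, np.array([1.0, 0.0]))
        assert np.allclose(st_.T[:, 1], 0.0)

    def test_orthogonal_column_unchanged(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        st_ = GreedyState.fresh(A, np.array([1.0, 0.0]))
        fr.deflate_columns(st_, np.array([1.0, 0.0]))
        assert np.allclose(st_.T[:, 1], [0.0, 1.0])

    def test_zero_basis_vector_rejected(self):
        A = np.eye(2)
        st_ = GreedyState.fresh(A, np.ones(2))
        with pytest.raises(ValueError):
            fr.deflate_columns(st_, np.zeros(2))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_post_deflation_orthogonality(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((10, 15))
        st_ = GreedyState.fresh(A, rng.standard_normal(10))
        u = rng.standard_normal(10)
        fr.deflate_columns(st_, u)
        assert np.max(np.abs(u @ st_.T)) < 1e-12 * np.abs(A).max() * np.linalg.norm(u)


class TestSchedule:
    def test_published_operating_point(self):
        """K0=6, L0=10 gives K: 6->8->9->10 and L: 10->7->5->4."""
        K, L, ks, ls = 6, 10, [6], [10]
        for i in range(1, 4):
            K, L = fr.update_schedule(K, L, i, 6, 10)
            ks.append(K); ls.append(L)
        assert ks == [6, 8, 9, 10]
        assert ls == [10, 7, 5, 4]

    def test_late_iterations_step_by_one(self):
        K, L = 6, 10
        for i in range(1, 40):
            K2, L2 = fr.update_schedule(K, L, i, 6, 10)
            if i >= 3:  # ceil(6/(i+1)^2) = 1 from i=3 on
                assert K2 - K == 1
            K, L = K2, L2

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 50))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_floored(self, K0, L0, i):
        K, L = fr.update_schedule(K0, L0, i, K0, L0)
        assert K > K0
        assert 1 <= L <= L0

    def test_invalid_iteration(self):
        with pytest.raises(ValueError):
            fr.update_schedule(6, 10, 0, 6, 10)


class TestResidualUpdate:
    def test_identity_selection_zeroes_residual(self):
        A = np.eye(4)
        y = np.eye(4)[2]
        st_ = GreedyState.fresh(A, y)
        q = q_vector(A, st_, 2)
        fr.update_residual(st_, q)
        assert np.allclose(st_.residual, 0.0)

    def test_residual_norm_nonincreasing(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((20, 50))
        A /= np.linalg.norm(A, axis=0)
        st_ = GreedyState.fresh(A, rng.standard_normal(20))
        cands = set(range(50))
        norms = [st_.residual_norm]
        for _ in range(5):
            _select_one(st_, cands)
            norms.append(st_.residual_norm)
        assert np.all(np.diff(norms) <= 1e-12)

    def test_basis_stays_orthogonal(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((30, 60))
        A /= np.linalg.norm(A, axis=0)
        st_ = GreedyState.fresh(A, rng.standard_normal(30))
        cands = set(range(60))
        for _ in range(8):
            _select_one(st_, cands)
        U = np.array(st_.basis)
        G = U @ U.T
        off = G - np.diag(np.diag(G))
        scale = np.outer(np.linalg.norm(U, axis=1), np.linalg.norm(U, axis=1))
        assert np.max(np.abs(off) / scale) < 1e-8
        # deflated candidate columns orthogonal to every basis vector
        unsel = sorted(set(range(60)) - set(st_.support))
        assert np.max(np.abs(U @ st_.T[:, unsel])) \
            < 1e-8 * np.abs(A).max() * np.abs(U).max()


class TestRestrictedLsq:
    def test_full_support_square_system(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        y = rng.standard_normal(5)
        c, res = fr.restricted_lsq(A, list(range(5)), y)
        assert np.allclose(c, np.linalg.solve(A, y))
        assert res < 1e-10

    def test_disjoint_orthogonal_support(self):
        A = np.eye(4)
        y = np.array([1.0, 0, 0, 0])
        _, res = fr.restricted_lsq(A, [2, 3], y)
        assert res == pytest.approx(1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        c, _ = fr.restricted_lsq(A, list(range(5)), y)
        c_ne = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(c, c_ne, atol=1e-10)

    def test_rank_deficiency_warns(self):
        A = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.warns(RuntimeWarning):
            fr.restricted_lsq(A, [0, 1], np.ones(3))


class TestNasols:
    def test_zero_measurement(self):
        A = np.eye(6)
        sol = fr.nasols(A, np.zeros(6), path_graph(6))
        assert np.allclose(sol.x_hat, 0.0)
        assert sol.converged
        assert len(sol.support_final) <= 10

    def test_identity_path_graph_spike(self):
        n = 10
        sol = fr.nasols(np.eye(n), np.eye(n)[5], path_graph(n),
                        fr.SolverConfig(K0=1, L0=1))
        assert sol.support_final == [5]
        assert np.allclose(sol.x_hat, np.eye(n)[5])
        assert sol.residual_norm < 1e-12

    def test_exact_recovery_connected_support(self, delaunay_mesh):
        _, graph = delaunay_mesh
        rng = np.random.default_rng(11)
        A = rng.standard_normal((64, 200))
        A /= np.linalg.norm(A, axis=0)
        x0, support = connected_sparse_signal(graph, rng, k=4)
        sol = fr.nasols(A, A @ x0, graph)
        assert support <= set(sol.support_all)
        assert np.linalg.norm(sol.x_hat - x0) / np.linalg.norm(x0) < 1e-6

    def test_dimension_mismatch(self, delaunay_mesh):
        _, graph = delaunay_mesh
        with pytest.raises(ValueError):
            fr.nasols(np.ones((4, 5)), np.ones(4), graph)

    def test_complete_graph_equals_asols(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((20, 40))
        A /= np.linalg.norm(A, axis=0)
        y = A[:, 3] + 0.5 * A[:, 7]
        s_n = fr.nasols(A, y, complete_graph(40))
        s_a = fr.asols(A, y)
        assert s_n.support_final == s_a.support_final
        assert np.array_equal(s_n.x_hat, s_a.x_hat)

    def test_scale_equivariance(self, delaunay_mesh):
        """Scaling (A, y, eps) by c > 0 leaves support and solution invariant."""
        _, graph = delaunay_mesh
        rng = np.random.default_rng(13)
        A = rng.standard_normal((64, 200))
        A /= np.linalg.norm(A, axis=0)
        x0, _ = connected_sparse_signal(graph, rng, k=3)
        y = A @ x0
        c = 1e-4
        s1 = fr.nasols(A, y, graph, fr.SolverConfig(eps=1e-8))
        s2 = fr.nasols(c * A, c * y, graph, fr.SolverConfig(eps=c * 1e-8))
        assert s1.support_final == s2.support_final
        assert np.allclose(s1.x_hat, s2.x_hat, rtol=1e-8)

    def test_relative_eps_mode(self, delaunay_mesh):
        _, graph = delaunay_mesh
        rng = np.random.default_rng(14)
        A = rng.standard_normal((64, 200))
        A /= np.linalg.norm(A, axis=0)
        x0, _ = connected_sparse_signal(graph, rng, k=3)
        sol = fr.nasols(1e-6 * A, 1e-6 * (A @ x0), graph,
                        fr.SolverConfig(eps=1e-6, eps_mode="rel"))
        assert sol.converged


class TestFixedSparsitySolvers:
    def test_ols_full_rank_exact(self):
        rng = np.random.default_rng(20)
        A = rng.standard_normal((6, 6)) + 4 * np.eye(6)
        y = rng.standard_normal(6)
        sol = fr.ols_fixed(A, y, 6)
        assert sol.residual_norm < 1e-8

    def test_orthonormal_ols_equals_top_correlations(self):
        rng = np.random.default_rng(21)
        Q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        y = rng.standard_normal(12)
        sol = fr.ols_fixed(Q, y, 4)
        want = np.argsort(-np.abs(Q.T @ y), kind="stable")[:4]
        assert sol.support_final == [int(j) for j in want]

    def test_two_column_hand_example(self):
        A = np.array([[1.0, 0.6], [0.0, 0.8]])
        sol = fr.ols_fixed(A, np.array([1.0, 0.0]), 1)
        assert sol.support_final == [0]

    def test_omp_gomp_ols_agree_on_orthonormal(self):
        rng = np.random.default_rng(22)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 10)))
        y = rng.standard_normal(10)
        s_ols = fr.ols_fixed(Q, y, 3)
        s_omp = fr.omp(Q, y, 3)
        s_gomp = fr.gomp(Q, y, 3, N_per_iter=1)
        assert set(s_ols.support_final) == set(s_omp.support_final) \
            == set(s_gomp.support_final)

    def test_zero_measurement_all_solvers(self):
        A = np.eye(5)
        y = np.zeros(5)
        for f in (lambda: fr.omp(A, y, 2), lambda: fr.gomp(A, y, 2),
                  lambda: fr.cosamp(A, y, 2), lambda: fr.ols_fixed(A, y, 2)):
            assert np.allclose(f().x_hat, 0.0)

    def test_cosamp_exact_sparse_recovery(self):
        """CoSaMP recovers a 2-sparse signal, verified against exhaustive
        best-support search on a small incoherent instance."""
        from itertools import combinations
        rng = np.random.default_rng(23)
        A = rng.standard_normal((20, 28))
        A /= np.linalg.norm(A, axis=0)
        x0 = np.zeros(28)
        x0[[4, 19]] = [1.2, -0.8]
        y = A @ x0
        sol = fr.cosamp(A, y, 2)
        best = None
        for sup in combinations(range(28), 2):
            _, res = fr.restricted_lsq(A, list(sup), y)
            if best is None or res < best[0]:
                best = (res, set(sup))
        assert set(sol.support_final) == best[1] == {4, 19}

    def test_invalid_K(self):
        A = np.eye(4)
        y = np.ones(4)
        for f in (fr.omp, fr.cosamp, fr.ols_fixed):
            with pytest.raises(ValueError):
                f(A, y, 0)

    def test_monotone_residual_all_solvers(self, delaunay_mesh):
        _, graph = delaunay_mesh
        rng = np.random.default_rng(24)
        A = rng.standard_normal((40, 200))
        A /= np.linalg.norm(A, axis=0)
        x0, _ = connected_sparse_signal(graph, rng, k=4)
        y = A @ x0 + 0.01 * rng.standard_normal(40)
        for sol in (fr.nasols(A, y, graph), fr.asols(A, y),
                    fr.ols_fixed(A, y, 8), fr.omp(A, y, 8),
                    fr.gomp(A, y, 8, 2)):
            rs = [h[2] for h in sol.history]
            assert np.all(np.diff(rs) <= 1e-10)


class TestSolverConfigValidation:
    @pytest.mark.parametrize("kw", [dict(K0=0), dict(L0=0), dict(eps=0.0),
                                    dict(max_iter=0), dict(eps_mode="bogus")])
    def test_rejects(self, kw):
        with pytest.raises(ValueError):
            fr.SolverConfig(**kw)
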