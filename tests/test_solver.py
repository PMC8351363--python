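"""Alternating least-squares solver: updates, convergence, baselines."""

import numpy as np
import pytest

from dhrls import (
    DhrlsModel,
    SolverParams,
    fit,
    fit_laprls,
    make_worked_example,
    objective,
    predict,
    update_alpha_d,
    update_alpha_g,
)
from dhrls.solver import fit_laprls_combined, load_model, save_model

from .conftest import random_association, random_psd_kernel


def _random_instance(rng, n, m):
    Y = random_association(rng, n, m)
    Kd = random_psd_kernel(rng, n)
    Kg = random_psd_kernel(rng, m, side="gene")
    return Y, Kd, Kg


class TestObjective:
    def test_zero_everything_gives_zero(self):
        model = DhrlsModel(
            alpha_d=np.zeros((2, 2)),
            alpha_g=np.zeros((2, 2)),
            K_d=np.eye(2),
            K_g=np.eye(2),
            L_d=np.zeros((2, 2)),
            L_g=np.zeros((2, 2)),
            params=SolverParams(lambda_d=0, lambda_g=0),
        )
        assert objective(model, np.zeros((2, 2))) == 0.0

    def test_zero_alphas_give_residual_term_only(self, rng):
        Y, Kd, Kg = _random_instance(rng, 4, 3)
        model = DhrlsModel(
            alpha_d=np.zeros((4, 3)),
            alpha_g=np.zeros((3, 4)),
            K_d=Kd.values,
            K_g=Kg.values,
            L_d=np.zeros((4, 4)),
            L_g=np.zeros((3, 3)),
            params=SolverParams(),
        )
        assert objective(model, Y) == pytest.approx(4 * np.sum(Y.values**2))

    def test_matches_term_by_term_oracle(self, rng):
        """Element-loop evaluation of every objective term."""
        Y, Kd, Kg = _random_instance(rng, 4, 3)
        Ld = random_psd_kernel(rng, 4).values
        Lg = random_psd_kernel(rng, 3).values
        ad = rng.standard_normal((4, 3))
        ag = rng.standard_normal((3, 4))
        p = SolverParams(lambda_d=0.7, lambda_g=0.3, beta=2.0)
        model = DhrlsModel(
            alpha_d=ad, alpha_g=ag, K_d=Kd.values, K_g=Kg.values,
            L_d=Ld, L_g=Lg, params=p,
        )
        resid = Kd.values @ ad + (Kg.values @ ag).T - 2 * Y.values
        expected = (
            np.sum(resid**2)
            + 0.7 * np.trace(ad.T @ Kd.values @ Ld @ Kd.values @ ad)
            + 0.3 * np.trace(ag.T @ Kg.values @ Lg @ Kg.values @ ag)
            + 2.0 * (np.sum(ad**2) + np.sum(ag**2))
        )
        assert objective(model, Y, p) == pytest.approx(expected, rel=1e-10)


class TestUpdates:
    def test_identity_kernel_ridge_case(self, rng):
        """alpha_g=0, lambda=0, K=I, beta=1: the update solves 2 alpha = 2Y."""
        Y = random_association(rng, 3, 4)
        p = SolverParams(lambda_d=0, lambda_g=0, beta=1, regularizer="none")
        model = DhrlsModel(
            alpha_d=np.zeros((3, 4)), alpha_g=np.zeros((4, 3)),
            K_d=np.eye(3), K_g=np.eye(4),
            L_d=np.zeros((3, 3)), L_g=np.zeros((4, 4)), params=p,
        )
        np.testing.assert_allclose(update_alpha_d(model, Y, p), Y.values, atol=1e-12)

    def test_scalar_hand_iteration(self):
        """1x1 instance: alpha_d from 0 is 1, then alpha_g = (2-1)/2 = 0.5."""
        p = SolverParams(lambda_d=0, lambda_g=0, beta=1, regularizer="none")
        model = DhrlsModel(
            alpha_d=np.zeros((1, 1)), alpha_g=np.zeros((1, 1)),
            K_d=np.eye(1), K_g=np.eye(1),
            L_d=np.zeros((1, 1)), L_g=np.zeros((1, 1)), params=p,
        )
        Y = np.ones((1, 1))
        model.alpha_d = update_alpha_d(model, Y, p)
        assert model.alpha_d[0, 0] == pytest.approx(1.0, abs=1e-14)
        model.alpha_g = update_alpha_g(model, Y, p)
        assert model.alpha_g[0, 0] == pytest.approx(0.5, abs=1e-14)

    def test_updates_are_stationary_points(self, rng):
        """Numerical gradient of the objective vanishes at each update."""
        Y, Kd, Kg = _random_instance(rng, 4, 3)
        p = SolverParams(lambda_d=0.5, lambda_g=0.8, beta=1.0, knn_k=2)
        model = fit(Y, Kd, Kg, p)
        eps = 1e-6
        base = objective(model, Y, p)
        g = np.zeros_like(model.alpha_g)
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                model.alpha_g[i, j] += eps
                g[i, j] = (objective(model, Y, p) - base) / eps
                model.alpha_g[i, j] -= eps
        assert np.abs(g).max() < 1e-3  # forward-difference noise floor


class TestFit:
    def test_all_zero_matrix_fixed_point_at_origin(self, rng):
        Kd = random_psd_kernel(rng, 3)
        Kg = random_psd_kernel(rng, 4, side="gene")
        p = SolverParams(lambda_d=0, lambda_g=0, regularizer="none")
        model = fit(np.zeros((3, 4)), Kd, Kg, p)
        np.testing.assert_allclose(model.alpha_d, 0.0, atol=1e-12)
        np.testing.assert_allclose(predict(model), 0.0, atol=1e-12)

    def test_scalar_fixed_point_two_thirds(self):
        """alpha <- (2 - alpha)/2 contracts to 2/3; F* = 2/3."""
        p = SolverParams(lambda_d=0, lambda_g=0, beta=1, n_iter=60, regularizer="none")
        model = fit(np.ones((1, 1)), np.eye(1), np.eye(1), p)
        assert model.alpha_d[0, 0] == pytest.approx(2 / 3, abs=1e-10)
        assert model.alpha_g[0, 0] == pytest.approx(2 / 3, abs=1e-10)
        assert predict(model)[0, 0] == pytest.approx(2 / 3, abs=1e-10)

    def test_objective_trace_monotone_on_random_instances(self, rng):
        """Each half-step exactly minimizes one convex block."""
        for _ in range(100):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            Y, Kd, Kg = _random_instance(rng, n, m)
            p = SolverParams(
                lambda_d=float(rng.random()), lambda_g=float(rng.random()),
                beta=0.5, knn_k=1, n_iter=4,
            )
            model = fit(Y, Kd, Kg, p)
            trace = model.objective_trace
            assert all(a >= b - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_als_reaches_joint_ridge_minimizer(self, rng):
        """With lambda=0 the ALS fixed point equals the stacked joint solve."""
        we = make_worked_example()["als_instance"]
        p = SolverParams(lambda_d=0, lambda_g=0, beta=we["beta"],
                         n_iter=400, regularizer="none")
        model = fit(we["Y"], we["K_d"], we["K_g"], p)
        np.testing.assert_allclose(model.alpha_d, we["expected_alpha_d"], atol=1e-6)
        np.testing.assert_allclose(model.alpha_g, we["expected_alpha_g"], atol=1e-6)

    def test_system_matrices_positive_definite(self, rng):
        from dhrls.solver import _system_matrix

        Y, Kd, Kg = _random_instance(rng, 5, 4)
        from dhrls.hypergraph import build_knn_hypergraph, hypergraph_laplacian

        L = hypergraph_laplacian(build_knn_hypergraph(Kd.values, 2)).values
        A = _system_matrix(Kd.values, L, lam=2.0, beta=0.7)
        assert np.linalg.eigvalsh(A).min() >= 0.7 - 1e-8

    def test_first_half_step_is_kernel_ridge(self, rng):
        """From alpha_g=0 with lambda=0, alpha_d = (K^2 + beta I)^{-1} 2KY."""
        Y, Kd, Kg = _random_instance(rng, 4, 3)
        p = SolverParams(lambda_d=0, lambda_g=0, beta=1.3, n_iter=1, regularizer="none")
        model = fit(Y, Kd, Kg, p)
        K = Kd.values
        expected_first = np.linalg.solve(K @ K + 1.3 * np.eye(4), 2 * K @ Y.values)
        # rerun a single alpha_d update from zero to compare
        model0 = DhrlsModel(
            alpha_d=np.zeros((4, 3)), alpha_g=np.zeros((3, 4)),
            K_d=K, K_g=Kg.values, L_d=np.zeros((4, 4)), L_g=np.zeros((3, 3)),
            params=p,
        )
        np.testing.assert_allclose(
            update_alpha_d(model0, Y, p), expected_first, atol=1e-10
        )

    def test_hypergraph_delta2_equals_graph_with_halved_lambda(self, rng):
        """Unit-weight pairwise hypergraph == ordinary Laplacian at lambda/2."""
        from dhrls.hypergraph import (
            Hypergraph,
            build_knn_hypergraph,
            graph_laplacian,
            hypergraph_laplacian,
        )

        Y, Kd, Kg = _random_instance(rng, 5, 4)
        G = build_knn_hypergraph(Kd.values, 1)
        G_unit = Hypergraph(G.H, np.ones(G.n_edges))
        Lh = hypergraph_laplacian(G_unit).values
        A_ind = G_unit.H @ G_unit.H.T - np.diag(G_unit.vertex_degrees)
        Ln = graph_laplacian(A_ind).values

        p_h = SolverParams(lambda_d=1.0, lambda_g=0.0, beta=1.0, n_iter=6)
        p_g = SolverParams(lambda_d=0.5, lambda_g=0.0, beta=1.0, n_iter=6)
        zero_g = np.zeros((4, 4))
        m_h = fit(Y, Kd, Kg, p_h, L_d=Lh, L_g=zero_g)
        m_g = fit(Y, Kd, Kg, p_g, L_d=Ln, L_g=zero_g)
        np.testing.assert_allclose(predict(m_h), predict(m_g), atol=1e-8)

    def test_permutation_equivariance_of_predictions(self, rng):
        Y, Kd, Kg = _random_instance(rng, 5, 4)
        p = SolverParams(lambda_d=0.5, lambda_g=0.5, beta=1.0, knn_k=2, n_iter=5)
        F = predict(fit(Y.values, Kd.values, Kg.values, p))
        perm = rng.permutation(5)
        Fp = predict(
            fit(Y.values[perm], Kd.values[np.ix_(perm, perm)], Kg.values, p)
        )
        np.testing.assert_allclose(Fp, F[perm], atol=1e-8)


class TestLapRls:
    def test_lambda_zero_returns_labels(self, rng):
        Y, Kd, _ = _random_instance(rng, 5, 4)
        F = fit_laprls(Y, Kd, side="disease", lam=0.0)
        np.testing.assert_allclose(F, Y.values, atol=1e-9)

    def test_identity_kernel_returns_labels(self, rng):
        Y = random_association(rng, 4, 3)
        F = fit_laprls(Y, np.eye(4), side="disease", lam=1.0)
        np.testing.assert_allclose(F, Y.values, atol=1e-10)

    def test_matches_explicit_inverse_oracle(self, rng):
        from dhrls.hypergraph import graph_laplacian

        Y, Kd, _ = _random_instance(rng, 5, 4)
        K = np.abs(Kd.values)
        lam = 0.8
        L = graph_laplacian(K).values
        expected = K @ np.linalg.inv(K + lam * L @ K) @ Y.values
        np.testing.assert_allclose(
            fit_laprls(Y, K, side="disease", lam=lam), expected, atol=1e-8
        )

    def test_combined_averages_both_sides(self, rng):
        Y, Kd, Kg = _random_instance(rng, 5, 4)
        Ka = np.abs(Kd.values)
        Kb = np.abs(Kg.values)
        F = fit_laprls_combined(Y, Ka, Kb, lam_d=0.5, lam_g=0.5)
        Fa = fit_laprls(Y, Ka, side="disease", lam=0.5)
        Fb = fit_laprls(Y, Kb, side="gene", lam=0.5)
        np.testing.assert_allclose(F, 0.5 * (Fa + Fb), atol=1e-12)


def test_model_save_load_round_trip(tmp_path, rng):
    Y, Kd, Kg = _random_instance(rng, 4, 3)
    p = SolverParams(knn_k=2, n_iter=3)
    model = fit(Y, Kd, Kg, p)
    path = tmp_path / "model.zip"
    save_model(model, path)
    loaded = load_model(path)
    np.testing.assert_array_equal(loaded.alpha_d, model.alpha_d)
    np.testing.assert_array_equal(loaded.K_g, model.K_g)
    assert loaded.params == p
    np.testing.assert_allclose(predict(loaded), predict(model))
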