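"""Penalized precision estimation: objective, solver, edges, penalty path."""

import numpy as np
import pytest

from ishnet.glasso import (
    GraphicalLassoPath,
    KernelGraphicalLasso,
    extract_edges,
    fit_sparse_precision,
    lambda_path_select,
    penalized_objective,
)
from ishnet.simulate import (
    SimulationConfig,
    ar1_process_precision,
    edge_precision_recall,
    sample_dependent_gaussian,
    tune_lambda_pilot,
)


def random_pd(rng, p, cond=5.0):
    A = rng.normal(size=(p, p))
    S = A @ A.T / p
    return S + cond * np.eye(p) / 5.0


def dense_oracle(S, lam, penalize_diagonal=True, max_iter=5000):
    """Minimize the same objective by proximal gradient descent on the dense
    matrix (soft-thresholding of Theta - eta*(S - Theta^-1), with backtracking
    to keep Theta positive-definite) — independent of the coordinate-descent
    solver under test."""
    p = S.shape[0]

    def objective(theta):
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return np.inf
        diag_pen = 1.0 if penalize_diagonal else 0.0
        l1 = np.abs(theta).sum() - (1 - diag_pen) * np.abs(np.diag(theta)).sum()
        return np.trace(S @ theta) - logdet + lam * l1

    def prox(M, t):
        out = np.sign(M) * np.maximum(np.abs(M) - t, 0.0)
        if not penalize_diagonal:
            np.fill_diagonal(out, np.diag(M))
        return out

    theta = np.linalg.inv(S + lam * np.eye(p))
    f = objective(theta)
    eta = 1.0
    for _ in range(max_iter):
        grad = S - np.linalg.inv(theta)
        while True:
            cand = prox(theta - eta * grad, eta * lam)
            cand = (cand + cand.T) / 2
            f_cand = objective(cand)
            if np.isfinite(f_cand) and f_cand <= f + 1e-15:
                break
            eta *= 0.5
            if eta < 1e-14:
                return theta, f
        if np.abs(cand - theta).max() < 1e-12:
            theta, f = cand, f_cand
            break
        theta, f = cand, f_cand
        eta *= 1.1
    return theta, f


class TestPenalizedObjective:
    def test_identity_no_penalty(self):
        assert penalized_objective(np.eye(4), np.eye(4), 0.0) == pytest.approx(4.0)

    def test_identity_with_penalty(self):
        assert penalized_objective(np.eye(3), np.eye(3), 0.5) == pytest.approx(4.5)

    def test_matches_eigendecomposition_oracle(self, rng):
        S = random_pd(rng, 5)
        theta = random_pd(rng, 5)
        lam = 0.3
        w = np.linalg.eigvalsh(theta)
        expected = (
            float(np.sum(S * theta.T)) - float(np.sum(np.log(w)))
            + lam * np.abs(theta).sum()
        )
        assert penalized_objective(S, theta, lam) == pytest.approx(
            expected, abs=1e-10
        )

    def test_non_pd_theta_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            penalized_objective(np.eye(2), np.diag([1.0, -1.0]), 0.1)


class TestFitSparsePrecision:
    def test_p2_edge_iff_offdiagonal_exceeds_lambda(self):
        """The 2-gene problem has a closed-form support rule; check it and the
        dense-optimizer oracle across an s x lambda grid."""
        for s in np.round(np.arange(-0.9, 0.95, 0.3), 10):
            for lam in (0.1, 0.3, 0.5):
                S = np.array([[1.0, s], [s, 1.0]])
                net = fit_sparse_precision(S, lam)
                expected_edge = abs(s) > lam
                assert (len(net.edges) == 1) == expected_edge
                theta_oracle, _ = dense_oracle(S, lam)
                oracle_edge = abs(theta_oracle[0, 1]) > 1e-4
                assert oracle_edge == expected_edge

    def test_saturation_lambda_gives_diagonal_theta(self, rng):
        for _ in range(5):
            S = random_pd(rng, 6)
            lam = np.abs(S - np.diag(np.diag(S))).max() + 1e-9
            net = fit_sparse_precision(S, lam)
            assert net.edges == set()
            off = net.theta - np.diag(np.diag(net.theta))
            assert np.abs(off).max() <= 1e-8

    def test_tiny_lambda_recovers_inverse(self, rng):
        for _ in range(5):
            S = random_pd(rng, 5)
            net = fit_sparse_precision(S, 1e-8, tol=1e-10 * np.abs(S).mean())
            assert np.abs(net.theta - np.linalg.inv(S)).max() <= 1e-3

    @pytest.mark.parametrize("penalize_diagonal", [True, False])
    def test_objective_matches_dense_convex_oracle(self, rng, penalize_diagonal):
        for p in (3, 5, 8):
            S = random_pd(rng, p)
            lam = 0.2
            net = fit_sparse_precision(S, lam, penalize_diagonal=penalize_diagonal)
            theta_o, obj_o = dense_oracle(S, lam, penalize_diagonal)
            diag_pen = 1.0 if penalize_diagonal else 0.0
            l1 = (
                np.abs(net.theta).sum()
                - (1 - diag_pen) * np.abs(np.diag(net.theta)).sum()
            )
            obj_mine = (
                np.trace(S @ net.theta)
                - np.linalg.slogdet(net.theta)[1]
                + lam * l1
            )
            assert abs(obj_mine - obj_o) <= 1e-4

    def test_offdiag_variant_matches_sklearn(self, rng):
        from sklearn.covariance import graphical_lasso as sk_glasso

        S = random_pd(rng, 6)
        lam = 0.15
        net = fit_sparse_precision(S, lam, penalize_diagonal=False)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = sk_glasso(S, alpha=lam, tol=1e-10, max_iter=500)
        assert np.abs(net.theta - prec).max() <= 1e-3

    def test_objective_not_above_initialization(self, rng):
        for _ in range(5):
            S = random_pd(rng, 6)
            lam = 0.3
            net = fit_sparse_precision(S, lam)
            theta_init = np.linalg.inv(np.diag(np.diag(S)) + lam * np.eye(6))
            assert net.objective_value <= penalized_objective(
                S, theta_init, lam
            ) + 1e-10

    def test_solution_symmetric(self, rng):
        S = random_pd(rng, 7)
        net = fit_sparse_precision(S, 0.2)
        assert np.abs(net.theta - net.theta.T).max() <= 1e-10

    def test_theta_positive_definite(self, rng):
        S = random_pd(rng, 7)
        net = fit_sparse_precision(S, 0.25)
        assert np.linalg.eigvalsh(net.theta).min() > 0

    def test_deterministic(self, rng):
        S = random_pd(rng, 6)
        n1 = fit_sparse_precision(S, 0.2)
        n2 = fit_sparse_precision(S, 0.2)
        np.testing.assert_array_equal(n1.theta, n2.theta)

    def test_invalid_lambda(self, rng):
        with pytest.raises(ValueError):
            fit_sparse_precision(np.eye(3), 0.0)


class TestExtractEdges:
    def test_diagonal_theta_no_edges(self):
        assert extract_edges(np.diag([1.0, 2.0, 3.0])) == set()

    def test_single_offdiagonal_pair(self):
        theta = np.eye(3)
        theta[0, 2] = theta[2, 0] = 0.5
        assert extract_edges(theta) == {(0, 2)}

    def test_matches_brute_force_scan(self, rng):
        theta = np.round(rng.normal(size=(8, 8)), 1) * (rng.uniform(size=(8, 8)) > 0.7)
        theta = (theta + theta.T) / 2
        np.fill_diagonal(theta, 1.0)
        tol = 1e-6
        expected = set()
        for i in range(8):
            for j in range(i + 1, 8):
                if abs(theta[i, j]) > tol:
                    expected.add((i, j))
        assert extract_edges(theta, tol) == expected


class TestLambdaPath:
    def test_all_empty_falls_back_to_smallest(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.3
        path = lambda_path_select(S, grid=[0.5, 1.0])
        assert all(len(n.edges) == 0 for n in path.networks)
        assert path.selected_lambda == 0.5

    def test_mean_degree_selection_on_simulated_truth(self):
        truth = ar1_process_precision(20)
        cfg = SimulationConfig(p=20, n=400, seed=3)
        X = sample_dependent_gaussian(cfg, truth, rho=0.0)
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / X.shape[0]
        path = lambda_path_select(
            S, grid=np.linspace(0.1, 0.9, 17), target_mean_degree=(2, 3)
        )
        assert 2.0 <= path.selected_network.mean_degree <= 3.0

    def test_edge_counts_non_increasing_along_grid(self, rng):
        S = random_pd(rng, 10)
        path = lambda_path_select(S, grid=np.linspace(0.05, 0.5, 10))
        counts = path.edge_counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_warm_start_agrees_with_cold_start(self, rng):
        S = random_pd(rng, 8)
        path = lambda_path_select(S, grid=np.linspace(0.1, 0.4, 4))
        for lam, net in zip(path.grid, path.networks):
            cold = fit_sparse_precision(S, lam)
            assert np.abs(net.theta - cold.theta).max() <= 1e-4


class TestSparsistency:
    def test_precision_recall_improve_with_sample_size(self):
        """Chain-recovery accuracy increases toward 1 as samples grow."""
        truth = ar1_process_precision(20)
        scores = {}
        for m in (50, 200, 1000):
            cfg = SimulationConfig(p=20, n=m, seed=11)
            lam = tune_lambda_pilot(truth, cfg, n_pilot=2)
            rng = np.random.default_rng(17)
            precs, recs = [], []
            for _ in range(3):
                X = sample_dependent_gaussian(cfg, truth, rho=0.0, rng=rng)
                Xc = X - X.mean(axis=0)
                S = Xc.T @ Xc / m
                net = fit_sparse_precision(S, lam)
                pr, rc = edge_precision_recall(net.edges, truth.true_edges)
                precs.append(pr)
                recs.append(rc)
            scores[m] = (np.mean(precs), np.mean(recs))
        f1 = {
            m: 2 * p * r / (p + r) if p + r else 0.0
            for m, (p, r) in scores.items()
        }
        assert f1[200] >= f1[50] - 0.05
        assert f1[1000] >= f1[200] - 0.05
        assert scores[1000][0] >= 0.85 and scores[1000][1] >= 0.9


class TestEstimators:
    def test_kernel_graphical_lasso_fitted_attributes(self, rng):
        S = random_pd(rng, 5)
        est = KernelGraphicalLasso(alpha=0.2).fit(S)
        assert est.precision_.shape == (5, 5)
        assert est.converged_
        assert est.get_params()["alpha"] == 0.2

    def test_path_estimator_scale_by_diagonal(self, rng):
        S = random_pd(rng, 6)
        scaled = GraphicalLassoPath(
            alphas=[0.1, 0.2], scale_by_diagonal=True
        ).fit(4.0 * S)
        plain = GraphicalLassoPath(
            alphas=[0.1, 0.2], scale_by_diagonal=False
        ).fit(4.0 * S)
        # relative scaling multiplies effective lambda by mean(diag)
        assert scaled.scale_ == pytest.approx(np.mean(np.diag(4.0 * S)))
        assert scaled.path_.grid != plain.path_.grid
        # scale-free property: same edges as the unscaled problem
        base = GraphicalLassoPath(alphas=[0.1, 0.2], scale_by_diagonal=True).fit(S)
        assert [len(n.edges) for n in scaled.path_.networks] == [
            len(n.edges) for n in base.path_.networks
        ]
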