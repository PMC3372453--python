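import numpy as np
import pytest
from scipy.optimize import LinearConstraint, minimize

from ncinet import (
    GRNMatrix,
    InferenceConfig,
    RowProblem,
    combine_estimates,
    infer_network,
    sgn_baseline,
    sign_accuracy,
    simulate_expression,
    solve_row_subproblem,
)


def row_objective(a, X1, x2, c):
    return np.sum((a @ X1 - x2) ** 2) + np.sum(c * np.abs(a))


def slsqp_row_oracle(X1, x2, c):
    """Independent QP solution via the positive/negative-part split."""
    n = X1.shape[0]

    def f(z):
        a = z[:n] - z[n:]
        return np.sum((a @ X1 - x2) ** 2) + np.sum(c * (z[:n] + z[n:]))

    res = minimize(
        f,
        np.zeros(2 * n),
        bounds=[(0, None)] * (2 * n),
        constraints=[LinearConstraint(np.ones(2 * n), -np.inf, 1.0)],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x[:n] - res.x[n:]


class TestRowSubproblem:
    def test_zero_target_gives_zero_row(self):
        rng = np.random.default_rng(0)
        p = RowProblem(rng.normal(size=(4, 6)), np.zeros(6), np.zeros(4))
        np.testing.assert_array_equal(solve_row_subproblem(p, 0.01), np.zeros(4))

    def test_huge_penalty_gives_zero_row(self):
        rng = np.random.default_rng(1)
        X1 = rng.normal(size=(4, 6))
        x2 = rng.normal(size=6)
        p = RowProblem(X1, x2, np.zeros(4))
        gamma = 1e6 * np.abs(X1 @ x2).max()
        np.testing.assert_array_equal(solve_row_subproblem(p, gamma), np.zeros(4))

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_matches_grid_search_oracle(self, seed):
        """2-gene instances against exhaustive search over the L1 ball."""
        rng = np.random.default_rng(seed)
        X1 = rng.normal(size=(2, 3))
        x2 = rng.normal(size=3) * 0.5
        w = rng.uniform(0, 1, 2)
        gamma, mu = 0.05, 0.5
        c = gamma + mu * w
        a = solve_row_subproblem(RowProblem(X1, x2, w), gamma, mu)
        grid = np.arange(-1.0, 1.0 + 1e-9, 1e-3)
        best = np.inf
        for u in grid:
            vs = grid[np.abs(grid) <= 1.0 - abs(u) + 1e-12]
            if not len(vs):
                continue
            resid = np.outer(np.full(len(vs), u), X1[0]) + np.outer(vs, X1[1]) - x2
            vals = np.sum(resid**2, axis=1) + c[0] * abs(u) + c[1] * np.abs(vs)
            best = min(best, vals.min())
        assert row_objective(a, X1, x2, c) <= best + 1e-2

    @pytest.mark.parametrize("seed", list(range(4)))
    def test_matches_slsqp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X1 = rng.normal(size=(5, 8))
        x2 = rng.normal(size=8) * 0.5
        w = rng.uniform(0, 1, 5)
        gamma, mu = 0.02, 0.2
        c = gamma + mu * w
        a = solve_row_subproblem(RowProblem(X1, x2, w), gamma, mu)
        a_o = slsqp_row_oracle(X1, x2, c)
        assert row_objective(a, X1, x2, c) <= row_objective(a_o, X1, x2, c) + 1e-6

    def test_row_stability_budget(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            X1 = rng.normal(size=(6, 10)) * 2.0
            x2 = rng.normal(size=10) * 3.0  # large target pushes to the boundary
            a = solve_row_subproblem(RowProblem(X1, x2, np.zeros(6)), 0.001)
            assert np.abs(a).sum() <= 1.0 + 1e-6


class TestInferNetwork:
    def test_zero_weights_equal_baseline(self, expr14):
        W = np.zeros((14, 14))
        np.testing.assert_allclose(
            infer_network(expr14, W, 0.02, 0.5).A,
            sgn_baseline(expr14, 0.02).A,
            atol=1e-9,
        )

    def test_uniform_weights_shift_gamma(self, expr14):
        """<1, |A|> is ||A||_1, so W = 1 with mu just adds to gamma."""
        a = infer_network(expr14, np.ones((14, 14)), 0.02, 0.01).A
        b = infer_network(expr14, None, 0.03, 0.0).A
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_every_row_satisfies_stability(self, expr14):
        A = infer_network(expr14, None, 0.008).A
        assert np.all(np.abs(A).sum(axis=1) <= 1.0 + 1e-6)

    def test_objective_no_worse_than_zero(self, expr14):
        A = infer_network(expr14, None, 0.02).A
        f = np.sum((A @ expr14.X1 - expr14.X2) ** 2) + 0.02 * np.abs(A).sum()
        assert f <= np.sum(expr14.X2**2) + 1e-9

    def test_sign_recovery_on_identifiable_network(self, cyclic5):
        """Noise-free, slowly decaying dynamics: sign pattern fully recovered."""
        X = simulate_expression(cyclic5, m=60, seed=2)
        est = infer_network(X, None, 0.001)
        assert sign_accuracy(est, cyclic5) > 0.9

    def test_sparsity_monotone_in_gamma(self, expr14):
        counts = [
            int((np.abs(infer_network(expr14, None, g).A) > 1e-4).sum())
            for g in (0.001, 0.01, 0.1, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_joint_solve_equals_stacked_rows(self):
        """Solving the whole matrix program at once (one generic convex
        solve over all n^2 coefficients) matches stacking the independent
        per-gene solutions, confirming the row decomposition."""
        rng = np.random.default_rng(3)
        n, m1 = 4, 7
        X1 = rng.normal(size=(n, m1))
        X2 = rng.normal(size=(n, m1)) * 0.5
        W = rng.uniform(0, 1, size=(n, n))
        gamma, mu = 0.05, 0.5
        C = gamma + mu * W

        def f(z):
            U = z[: n * n].reshape(n, n)
            V = z[n * n :].reshape(n, n)
            A = U - V
            return np.sum((A @ X1 - X2) ** 2) + np.sum(C * (U + V))

        cons = []
        for i in range(n):
            row = np.zeros(2 * n * n)
            row[i * n : (i + 1) * n] = 1.0
            row[n * n + i * n : n * n + (i + 1) * n] = 1.0
            cons.append(LinearConstraint(row, -np.inf, 1.0))
        res = minimize(
            f,
            np.zeros(2 * n * n),
            bounds=[(0, None)] * (2 * n * n),
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        stacked = np.vstack(
            [
                solve_row_subproblem(RowProblem(X1, X2[i], W[i]), gamma, mu)
                for i in range(n)
            ]
        )
        f_stacked = np.sum((stacked @ X1 - X2) ** 2) + np.sum(
            C * np.abs(stacked)
        )
        assert abs(res.fun - f_stacked) <= 1e-4 * (1 + abs(res.fun))


class TestCombineEstimates:
    def test_single_estimate_unchanged(self):
        e = GRNMatrix(np.array([[0.1, -0.2], [0.0, 0.3]]))
        np.testing.assert_array_equal(combine_estimates([e]).A, e.A)

    def test_disjoint_supports_union(self):
        a = GRNMatrix(np.array([[0.5, 0.0], [0.0, 0.0]]))
        b = GRNMatrix(np.array([[0.0, 0.0], [0.0, -0.4]]))
        np.testing.assert_array_equal(
            combine_estimates([a, b]).A, [[0.5, 0.0], [0.0, -0.4]]
        )

    def test_largest_magnitude_wins_with_sign(self):
        a = GRNMatrix(np.array([[0.3]]))
        b = GRNMatrix(np.array([[-0.5]]))
        assert combine_estimates([a, b]).A[0, 0] == -0.5

    def test_ties_break_to_earliest(self):
        a = GRNMatrix(np.array([[0.5]]))
        b = GRNMatrix(np.array([[-0.5]]))
        assert combine_estimates([a, b]).A[0, 0] == 0.5

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            combine_estimates([])


class TestInferenceConfig:
    def test_size_adapted_grids(self):
        c14 = InferenceConfig.for_size(14)
        assert c14.gamma_list == [0.05, 0.02, 0.008] and c14.gamma_tau == 0.02
        c50 = InferenceConfig.for_size(50)
        assert c50.gamma_list == [0.02, 0.005, 0.001] and c50.gamma_tau == 0.005

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            InferenceConfig(gamma_list=[0.1, -0.2])
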