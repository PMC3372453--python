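import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncinet import (
    BlockPCAProblem,
    block_pca_objective,
    block_pca_oracle,
    block_pca_split,
    soft_threshold,
    svt,
    weighted_soft_threshold,
)

from conftest import cloud_weight_matrix


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "t,eps,expected",
        [(1.5, 1.0, 0.5), (-0.3, 1.0, 0.0), (-2.0, 0.5, -1.5), (0.0, 1.0, 0.0)],
    )
    def test_scalar_definition(self, t, eps, expected):
        assert soft_threshold(t, eps) == pytest.approx(expected)

    @given(st.floats(-100, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_zero_threshold_is_identity(self, x):
        assert soft_threshold(x, 0.0) == x

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)

    def test_elementwise_on_matrices(self):
        X = np.array([[2.0, -0.5], [0.1, -3.0]])
        np.testing.assert_allclose(
            soft_threshold(X, 1.0), [[1.0, 0.0], [0.0, -2.0]]
        )


class TestWeightedSoftThreshold:
    def test_zero_weights_identity(self):
        X = np.random.default_rng(0).normal(size=(4, 4))
        np.testing.assert_array_equal(
            weighted_soft_threshold(X, np.zeros((4, 4))), X
        )

    def test_constant_weights_degenerate_to_scalar(self):
        X = np.random.default_rng(1).normal(size=(4, 4))
        np.testing.assert_allclose(
            weighted_soft_threshold(X, 0.3 * np.ones((4, 4))),
            soft_threshold(X, 0.3),
        )

    def test_mixed_weights_entrywise(self):
        X = np.array([[1.0, -2.0], [0.2, 3.0]])
        W = np.array([[0.5, 1.0], [0.5, 0.0]])
        np.testing.assert_allclose(
            weighted_soft_threshold(X, W), [[0.5, -1.0], [0.0, 3.0]]
        )


class TestSVT:
    def test_diagonal_closed_form(self):
        np.testing.assert_allclose(
            svt(np.diag([3.0, 1.0]), 2.0), np.diag([1.0, 0.0]), atol=1e-12
        )

    def test_large_threshold_annihilates(self):
        X = np.random.default_rng(2).normal(size=(4, 4))
        tau = np.linalg.norm(X, 2) * 1.01
        np.testing.assert_allclose(svt(X, tau), 0.0, atol=1e-12)

    def test_nuclear_norm_of_output(self):
        X = np.random.default_rng(3).normal(size=(5, 5))
        s = np.linalg.svd(X, compute_uv=False)
        out_nuc = np.linalg.svd(svt(X, 0.5), compute_uv=False).sum()
        assert out_nuc == pytest.approx(np.maximum(s - 0.5, 0.0).sum(), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nonexpansive(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        assert np.linalg.norm(svt(X, 0.7) - svt(Y, 0.7)) <= np.linalg.norm(
            X - Y
        ) + 1e-12


class TestObjective:
    def test_zero_solution(self):
        p = BlockPCAProblem(W1=np.zeros((3, 3)))
        assert block_pca_objective(np.zeros((3, 3)), np.zeros((3, 3)), p) == 0.0

    def test_all_ones_low_rank_part(self):
        n = 6
        p = BlockPCAProblem(W1=np.zeros((n, n)))
        val = block_pca_objective(np.ones((n, n)), np.zeros((n, n)), p)
        assert val == pytest.approx(n)  # rank one, sigma = n


class TestSplitSolver:
    def test_one_iteration_on_infinite_tolerance(self):
        W1 = cloud_weight_matrix(6, seed=0)
        _, _, report = block_pca_split(
            BlockPCAProblem(W1=W1), eps1=np.inf, eps2=np.inf
        )
        assert report.iterations == 1 and report.converged

    def test_feasibility_at_termination(self):
        W1 = cloud_weight_matrix(8, seed=1)
        p = BlockPCAProblem(W1=W1)
        L, E, report = block_pca_split(p, eps1=1e-6, eps2=1e-6)
        assert report.converged
        primal = np.sqrt(
            np.linalg.norm(p.D - L - E) ** 2 + 0.0
        )  # L = U at the fixed point up to eps
        assert report.primal_residual <= 1e-6

    def test_symmetry_preserved(self):
        W1 = cloud_weight_matrix(7, seed=2)
        W1 = 0.5 * (W1 + W1.T)
        L, E, _ = block_pca_split(BlockPCAProblem(W1=W1), max_iter=300)
        np.testing.assert_allclose(L, L.T, atol=1e-10)
        np.testing.assert_allclose(E, E.T, atol=1e-10)

    def test_matches_robust_pca_without_weights(self):
        """With W1 = 0 the weighted term vanishes and the model reduces to
        plain robust PCA; the independent smoothed solver agrees."""
        n = 8
        p = BlockPCAProblem(W1=np.zeros((n, n)), lambda1=0.05 / np.sqrt(n))
        L, E, _ = block_pca_split(p)
        Lo, Eo = block_pca_oracle(p)
        fs = block_pca_objective(L, E, p)
        fo = block_pca_objective(Lo, Eo, p)
        assert abs(fs - fo) <= 1e-3 * abs(fo)

    def test_two_block_weight_pattern_confines_support(self):
        """Zero weights inside blocks {1,2,3} and {4,5}, large across: the
        recovered low-rank support stays inside the diagonal blocks."""
        W1 = np.full((5, 5), 50.0)
        for blk in ([0, 1, 2], [3, 4]):
            W1[np.ix_(blk, blk)] = 0.0
        np.fill_diagonal(W1, 0.0)
        L, _, _ = block_pca_split(BlockPCAProblem(W1=W1))
        S = np.abs(L) > 1e-6
        allowed = np.zeros((5, 5), dtype=bool)
        allowed[np.ix_([0, 1, 2], [0, 1, 2])] = True
        allowed[np.ix_([3, 4], [3, 4])] = True
        assert S.any()
        assert not (S & ~allowed).any()

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_oracle_equivalence_on_point_clouds(self, n):
        p = BlockPCAProblem(W1=cloud_weight_matrix(n, seed=40 + n))
        L, E, _ = block_pca_split(p)
        Lo, Eo = block_pca_oracle(p)
        fs = block_pca_objective(L, E, p)
        fo = block_pca_objective(Lo, Eo, p)
        assert abs(fs - fo) <= 1e-3 * abs(fo)

    def test_sparsity_monotone_in_lambda1(self):
        W1 = cloud_weight_matrix(30, seed=7)
        lam2 = 1.0 / np.sqrt(30)
        counts = []
        for frac in (0.2, 0.4, 0.6, 0.7):
            L, _, _ = block_pca_split(
                BlockPCAProblem(W1=W1, lambda1=frac * lam2, lambda2=lam2)
            )
            counts.append(int((np.abs(L) > 1e-6).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nonconvergence_reported_not_raised(self):
        W1 = cloud_weight_matrix(6, seed=3)
        _, _, report = block_pca_split(
            BlockPCAProblem(W1=W1), eps1=1e-14, eps2=1e-14, max_iter=5
        )
        assert not report.converged and report.iterations == 5

    def test_invalid_penalty_ordering_rejected(self):
        with pytest.raises(ValueError):
            BlockPCAProblem(W1=np.zeros((4, 4)), lambda1=1.0, lambda2=0.5)
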