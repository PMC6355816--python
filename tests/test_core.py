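"""Ridge inverse regression and the closed-form LOOCV error profile."""

import numpy as np
import pytest

from multppe import (LambdaGrid, build_design, default_grid,
                     loocv_errors_fast, loocv_errors_matrix,
                     loocv_errors_naive, ridge_fit, svd_cache)


def naive_press_ols(D, x):
    """Independent PRESS oracle: explicit OLS refits via lstsq."""
    n = D.shape[0]
    T = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(D[keep], x[keep], rcond=None)
        T += (x[i] - D[i] @ beta) ** 2
    return T


class TestBuildDesign:
    def test_prepends_intercept(self):
        Y = np.arange(6.0).reshape(3, 2)
        D = build_design(Y)
        assert D.shape == (3, 3)
        assert np.array_equal(D[:, 0], np.ones(3))
        assert np.array_equal(D[:, 1:], Y)

    def test_rejects_zero_phenotypes(self):
        with pytest.raises(ValueError, match="at least one phenotype"):
            build_design(np.empty((3, 0)))

    def test_duplicate_columns_allowed(self, rng):
        y = rng.standard_normal((8, 1))
        D = build_design(np.hstack([y, y]))
        assert D.shape == (8, 3)  # rank deficiency is the penalty's problem

    def test_rejects_nan(self):
        Y = np.ones((4, 2))
        Y[1, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            build_design(Y)


class TestRidgeFit:
    def test_interpolates_at_zero_penalty(self, rng):
        D = build_design(rng.standard_normal((12, 3)))
        beta_true = rng.standard_normal(4)
        beta = ridge_fit(D, D @ beta_true, lam=0.0)
        assert np.allclose(beta, beta_true, atol=1e-9)

    def test_matches_direct_inverse_oracle(self, rng):
        D = build_design(rng.standard_normal((10, 3)))
        x = rng.standard_normal(10)
        beta = ridge_fit(D, x, lam=2.0)
        oracle = np.linalg.inv(D.T @ D + 2.0 * np.eye(4)) @ D.T @ x
        assert np.allclose(beta, oracle, rtol=1e-12)

    def test_huge_penalty_kills_all_coefficients(self, rng):
        D = build_design(rng.standard_normal((15, 2)))
        beta = ridge_fit(D, rng.standard_normal(15), lam=1e12)
        # intercept is penalized too, so every coefficient collapses
        assert np.all(np.abs(beta) < 1e-9)

    def test_rank_deficient_at_zero_raises(self, rng):
        y = rng.standard_normal((9, 1))
        D = build_design(np.hstack([y, y]))
        with pytest.raises(np.linalg.LinAlgError):
            ridge_fit(D, rng.standard_normal(9), lam=0.0)


class TestSVDCache:
    def test_shrinkage_and_leverage_contracts(self, toy_data):
        Y, _ = toy_data
        grid = default_grid()
        cache = svd_cache(build_design(Y), grid)
        assert np.allclose(cache.U.T @ cache.U, np.eye(Y.shape[1] + 1),
                           atol=1e-12)
        assert np.all((cache.C >= 0) & (cache.C <= 1))
        # shrinkage strictly decreasing along the (increasing) penalty grid
        assert np.all(np.diff(cache.C, axis=1) < 0)
        assert np.all((cache.H >= 0) & (cache.H < 1))
        # trace identity: column sums of H equal the summed shrinkages
        assert np.allclose(cache.H.sum(axis=0), cache.C.sum(axis=0),
                           rtol=1e-10)

    def test_leverages_match_direct_inverse(self, rng):
        D = build_design(rng.standard_normal((20, 3)))
        grid = default_grid()
        cache = svd_cache(D, grid)
        for m, lam in enumerate(grid.lambdas):
            Hm = np.diag(D @ np.linalg.inv(D.T @ D + lam * np.eye(4)) @ D.T)
            assert np.allclose(cache.H[:, m], Hm, rtol=1e-10)

    def test_orthonormal_design_shrinkage_values(self):
        # columns orthonormal => all d_j = 1 => c = 1/(1+lambda)
        D = np.linalg.qr(np.random.default_rng(3).standard_normal((12, 3)))[0]
        cache = svd_cache(D, LambdaGrid.from_lambdas([0.0, 1.0]))
        assert np.allclose(cache.C[:, 0], 1.0)
        assert np.allclose(cache.C[:, 1], 0.5)

    def test_too_few_individuals_raises(self, rng):
        with pytest.raises(ValueError, match="n >= K\\+1"):
            svd_cache(build_design(rng.standard_normal((3, 4))))


class TestLOOCV:
    def test_naive_hand_solved_instance(self):
        # n=5, K=1, lambda=1: each leave-one-out ridge is a 2x2 system that
        # can be inverted in closed form.
        y = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, 0.0, 2.0, 1.0, 2.0])
        D = build_design(y[:, None])
        lam = 1.0
        expected = 0.0
        for i in range(5):
            keep = np.arange(5) != i
            yk, xk = y[keep], x[keep]
            a = len(yk) + lam
            b = yk.sum()
            c = (yk**2).sum() + lam
            det = a * c - b * b
            b0 = (c * xk.sum() - b * (yk * xk).sum()) / det
            b1 = (-b * xk.sum() + a * (yk * xk).sum()) / det
            expected += (x[i] - b0 - b1 * y[i]) ** 2
        T = loocv_errors_naive(D, x, LambdaGrid.from_lambdas([lam]))
        assert np.allclose(T, [expected], rtol=1e-12)

    def test_constant_response_has_positive_error(self):
        # penalty shrinks the intercept, so even x = const is mispredicted
        D = build_design(np.array([[0.5], [1.0], [2.0]]))
        T = loocv_errors_naive(D, np.ones(3), LambdaGrid.from_lambdas([1.0]))
        assert T[0] > 0

    @pytest.mark.parametrize("seed", range(6))
    def test_fast_equals_naive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 61))
        K = int(rng.integers(1, 9))
        Y = rng.standard_normal((n, K))
        x = rng.binomial(2, 0.3, n).astype(float)
        D = build_design(Y)
        grid = default_grid()
        T_fast = loocv_errors_fast(svd_cache(D, grid), x)
        T_naive = loocv_errors_naive(D, x, grid)
        assert np.max(np.abs(T_fast - T_naive) / T_naive) <= 1e-8

    def test_zero_penalty_reproduces_press(self, rng):
        # lambda = 0 with a full-rank design is ordinary least squares;
        # the fast path must reproduce the PRESS statistic from refits
        Y = rng.standard_normal((30, 4))
        x = rng.standard_normal(30)
        D = build_design(Y)
        grid = LambdaGrid.from_lambdas([0.0, 1.0])
        T = loocv_errors_fast(svd_cache(D, grid), x)
        assert np.allclose(T[0], naive_press_ols(D, x), rtol=1e-8)

    def test_closed_form_residual_identity(self, rng):
        # (x_i - xhat_i)/(1 - h_i) equals the refit leave-one-out residual
        Y = rng.standard_normal((15, 2))
        x = rng.standard_normal(15)
        D = build_design(Y)
        lam = 7.0
        cache = svd_cache(D, LambdaGrid.from_lambdas([lam]))
        beta = ridge_fit(D, x, lam)
        shortcut = (x - D @ beta) / (1.0 - cache.H[:, 0])
        for i in range(15):
            keep = np.arange(15) != i
            beta_i = ridge_fit(D[keep], x[keep], lam)
            assert np.isclose(shortcut[i], x[i] - D[i] @ beta_i, rtol=1e-8)

    def test_leverage_guard_names_offending_rows(self, rng):
        # square design: at lambda = 0 every leverage is exactly 1
        D = build_design(rng.standard_normal((3, 2)))
        cache = svd_cache(D, LambdaGrid.from_lambdas([0.0]))
        with pytest.raises(ValueError, match="leverage"):
            loocv_errors_fast(cache, rng.standard_normal(3))

    def test_duplicate_rows_are_stable(self, rng):
        Y = rng.standard_normal((10, 2))
        x = rng.standard_normal(10)
        Y2, x2 = np.vstack([Y, Y[:1]]), np.append(x, x[0])
        T = loocv_errors_fast(svd_cache(build_design(Y2), default_grid()), x2)
        assert np.all(np.isfinite(T))

    def test_block_equals_column_loop(self, toy_data, rng):
        # the vectorized block path agrees with per-column evaluation
        Y, x = toy_data
        cache = svd_cache(build_design(Y), default_grid())
        X = np.column_stack([rng.permutation(x) for _ in range(9)])
        T_block = loocv_errors_matrix(cache, X)
        T_loop = np.vstack([loocv_errors_fast(cache, X[:, j])
                            for j in range(9)])
        assert np.allclose(T_block, T_loop, rtol=1e-12, atol=0)
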