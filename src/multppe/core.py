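"""Ridge inverse regression and its leave-one-out cross-validation error.

The test statistic of the MultP-PE method is the LOOCV prediction error of a
ridge regression of the genotype on the phenotypes (the *inverse* regression:
one test covers all K phenotypes jointly),

    T_lambda = sum_i (x_i - xhat_{-i}^lambda)^2,

where xhat_{-i}^lambda is the prediction for individual i from a ridge fit
that excludes individual i. Low values of T_lambda indicate association.

Two routes to T_lambda are provided:

* :func:`loocv_errors_naive` refits the ridge n times per penalty — the
  brute-force definition, used as the oracle in tests;
* :func:`loocv_errors_fast` uses the closed-form LOOCV identity
  ``x_i - xhat_{-i} = (x_i - xhat_i) / (1 - h_i)`` with leverages taken from
  a single thin SVD of the design (:func:`svd_cache`), so that permuting or
  swapping the genotype vector costs only two small matrix products.

The design matrix carries an explicit intercept column and the penalty is
applied to *all* K+1 coefficients, intercept included — this matches the
estimator ``beta_hat = (Y'Y + lambda I)^{-1} Y'x`` with the ones column
inside Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_LOG_LAMBDAS",
    "LambdaGrid",
    "default_grid",
    "build_design",
    "ridge_fit",
    "loocv_errors_naive",
    "SVDCache",
    "svd_cache",
    "loocv_errors_fast",
    "loocv_errors_matrix",
]

#: Default grid of log-penalties (natural log): lambda = 1 ... e^4.5 ~ 90.
DEFAULT_LOG_LAMBDAS = (0.0, 1.0, 2.0, 3.0, 3.5, 3.8, 4.0, 4.5)

#: Guard on 1 - h_i before the LOOCV division; breaching it is an error.
LEVERAGE_GUARD = 1e-10


@dataclass(frozen=True)
class LambdaGrid:
    """Strictly increasing grid of ridge penalties, stored on the log scale."""

    log_lambdas: np.ndarray

    def __post_init__(self) -> None:
        ll = np.asarray(self.log_lambdas, dtype=float)
        if ll.ndim != 1 or ll.size < 1:
            raise ValueError("lambda grid must be a non-empty 1-d sequence")
        if np.any(np.diff(ll) <= 0):
            raise ValueError("log-lambda grid must be strictly increasing")
        object.__setattr__(self, "log_lambdas", ll)

    @property
    def lambdas(self) -> np.ndarray:
        return np.exp(self.log_lambdas)

    def __len__(self) -> int:
        return self.log_lambdas.size

    @classmethod
    def from_lambdas(cls, lambdas) -> "LambdaGrid":
        """Build a grid from penalties on the natural scale (0 is allowed)."""
        lam = np.asarray(lambdas, dtype=float)
        if np.any(lam < 0):
            raise ValueError("penalties must be non-negative")
        with np.errstate(divide="ignore"):
            return cls(np.log(lam))


def default_grid() -> LambdaGrid:
    """The eight-point penalty grid used throughout: log lambda = 0 ... 4.5."""
    return LambdaGrid(np.array(DEFAULT_LOG_LAMBDAS))


def build_design(phenotypes: np.ndarray) -> np.ndarray:
    """Prepend an intercept column of ones to the n x K phenotype matrix.

    Returns the n x (K+1) design of the inverse regression. Rank deficiency
    (e.g. duplicated phenotype columns) is deliberately not checked here —
    the ridge penalty handles it.
    """
    Y = np.asarray(phenotypes, dtype=float)
    if Y.ndim != 2:
        raise ValueError("phenotype matrix must be 2-dimensional")
    n, K = Y.shape
    if K < 1:
        raise ValueError("at least one phenotype is required")
    if n < 2:
        raise ValueError("at least two individuals are required")
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotype matrix contains non-finite values; "
                         "handle missing data before building the design")
    return np.column_stack([np.ones(n), Y])


def ridge_fit(design: np.ndarray, x: np.ndarray, lam: float) -> np.ndarray:
    """Solve the ridge normal equations (Y'Y + lambda I) beta = Y'x.

    All K+1 coefficients, including the intercept, are penalized. Returns
    beta_hat of length K+1. With ``lam == 0`` the design must be full rank.
    """
    Y = np.asarray(design, dtype=float)
    x = np.asarray(x, dtype=float)
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    if Y.shape[0] != x.shape[0]:
        raise ValueError("design and genotype lengths differ")
    p = Y.shape[1]
    if lam == 0 and np.linalg.matrix_rank(Y) < p:
        raise np.linalg.LinAlgError(
            "design is rank deficient; lambda = 0 has no unique solution")
    A = Y.T @ Y + lam * np.eye(p)
    return np.linalg.solve(A, Y.T @ x)


def loocv_errors_naive(design: np.ndarray, x: np.ndarray,
                       grid: LambdaGrid) -> np.ndarray:
    """LOOCV prediction error by explicit refitting — the oracle path.

    For each penalty on the grid, refits the ridge n times, each time with
    one individual held out, and accumulates the squared prediction errors.
    O(n * M) linear solves; used to validate :func:`loocv_errors_fast`.
    """
    Y = np.asarray(design, dtype=float)
    x = np.asarray(x, dtype=float)
    n = Y.shape[0]
    T = np.zeros(len(grid))
    for m, lam in enumerate(grid.lambdas):
        for i in range(n):
            keep = np.arange(n) != i
            beta = ridge_fit(Y[keep], x[keep], lam)
            T[m] += (x[i] - Y[i] @ beta) ** 2
    return T


@dataclass
class SVDCache:
    """Per-dataset decomposition shared by every penalty, permutation and SNP.

    From the thin SVD ``Y = U diag(d) Vt`` of the n x (K+1) design:

    * ``C[j, m] = d_j^2 / (d_j^2 + lambda_m)`` — per-component shrinkage;
    * ``H[i, m] = h_i^{lambda_m}`` — ridge leverages, the diagonal of
      ``Y (Y'Y + lambda_m I)^{-1} Y'``.

    Only the genotype vector changes across permutations and SNPs, so U, C
    and H are computed once per phenotype set.
    """

    U: np.ndarray
    d: np.ndarray
    V: np.ndarray
    C: np.ndarray
    H: np.ndarray
    grid: LambdaGrid
    _bad_rows: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # rows whose leverage makes the LOOCV division degenerate, per lambda
        self._bad_rows = np.max(self.H, axis=1) >= 1.0 - LEVERAGE_GUARD

    @property
    def n(self) -> int:
        return self.U.shape[0]

    def check_leverages(self) -> None:
        if self._bad_rows.any():
            rows = np.flatnonzero(self._bad_rows)
            raise ValueError(
                f"leverage >= 1 - {LEVERAGE_GUARD:g} for rows {rows.tolist()}; "
                "leave-one-out prediction is degenerate for these individuals")


def svd_cache(design: np.ndarray, grid: LambdaGrid | None = None) -> SVDCache:
    """Thin SVD of the design plus shrinkage factors and leverages per penalty.

    Requires n >= K+1 so that the thin SVD retains all K+1 components; with
    fewer individuals than coefficients the leverages of the printed identity
    are not defined and the caller should subsample phenotypes instead.
    """
    if grid is None:
        grid = default_grid()
    Y = np.asarray(design, dtype=float)
    n, p = Y.shape
    if n < p:
        raise ValueError(
            f"n = {n} individuals < K+1 = {p} coefficients: the thin SVD "
            "route needs n >= K+1; reduce the number of phenotypes")
    U, d, Vt = np.linalg.svd(Y, full_matrices=False)
    lambdas = grid.lambdas
    d2 = d**2
    with np.errstate(invalid="ignore"):
        C = d2[:, None] / (d2[:, None] + lambdas[None, :])
    C = np.nan_to_num(C, nan=0.0)  # d_j = 0 and lambda = 0: component absent
    H = (U * U) @ C
    return SVDCache(U=U, d=d, V=Vt.T, C=C, H=H, grid=grid)


def loocv_errors_matrix(cache: SVDCache, X: np.ndarray) -> np.ndarray:
    """LOOCV errors for every column of an n x J genotype block at once.

    Returns a J x M matrix of T values. This is the workhorse of the
    permutation engine: one U'X product covers all J columns, then each
    penalty costs one rank-(K+1) reconstruction. Column j passed alone gives
    bit-identical output, so looping and blocking agree exactly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != cache.n:
        raise ValueError("genotype block must be n x J")
    cache.check_leverages()
    XK = cache.U.T @ X                      # (K+1) x J
    M = len(cache.grid)
    T = np.empty((X.shape[1], M))
    for m in range(M):
        fitted = cache.U @ (cache.C[:, m : m + 1] * XK)
        Q = (X - fitted) / (1.0 - cache.H[:, m : m + 1])
        T[:, m] = np.einsum("ij,ij->j", Q, Q)
    return T


def loocv_errors_fast(cache: SVDCache, x: np.ndarray) -> np.ndarray:
    """Closed-form LOOCV error profile for one genotype vector.

    Computes x^(K) = U'x, fitted values U(c_lambda * x^(K)), then the
    LOOCV residuals (x - xhat) / (1 - h) and their column sums of squares.
    Agrees with :func:`loocv_errors_naive` to floating-point accuracy.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("genotype must be a 1-d vector")
    return loocv_errors_matrix(cache, x[:, None])[0]
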