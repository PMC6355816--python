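"""Covariate and population-stratification adjustment.

Covariates enter MultP-PE by residualization: each phenotype is regressed on
an intercept plus the covariates and replaced by its OLS residual before the
test. Population structure is handled the same way with ancestry principal
components, except that the genotype vector is residualized too (it becomes
real-valued, no longer 0/1/2 counts — the test does not care).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "residualize",
    "residualize_phenotypes",
    "residualize_for_stratification",
    "compute_pcs",
]


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    if Z.shape[0] != n:
        raise ValueError("covariate matrix row count does not match n")
    return np.column_stack([np.ones(n), Z])


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of each column of ``values`` on intercept + covariates."""
    V = np.asarray(values, dtype=float)
    squeeze = V.ndim == 1
    if squeeze:
        V = V[:, None]
    Z = _with_intercept(covariates, V.shape[0])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError(
            "covariate design (with intercept) is rank deficient")
    coef, *_ = np.linalg.lstsq(Z, V, rcond=None)
    R = V - Z @ coef
    return R[:, 0] if squeeze else R


def residualize_phenotypes(phenotypes: np.ndarray,
                           covariates: np.ndarray) -> np.ndarray:
    """Replace each phenotype by its residual on the covariates."""
    return residualize(phenotypes, covariates)


def residualize_for_stratification(phenotypes: np.ndarray,
                                   x: np.ndarray,
                                   pcs: np.ndarray | None):
    """Residualize both phenotypes and genotype on the top ancestry PCs.

    With ``pcs`` empty or None both are merely centered (intercept-only
    regression). Returns ``(adjusted_phenotypes, adjusted_genotype)``.
    """
    if pcs is not None and np.asarray(pcs).size == 0:
        pcs = None
    return residualize(phenotypes, pcs), residualize(x, pcs)


def compute_pcs(genotype_matrix: np.ndarray, L: int = 10) -> np.ndarray:
    """Top-L principal component scores of a genotype panel.

    Columns (SNPs) are centered and scaled to unit variance — the standard
    ancestry-PC convention — after dropping monomorphic SNPs; scores are the
    left singular vectors scaled by the singular values, so PC columns are
    mutually orthogonal.
    """
    G = np.asarray(genotype_matrix, dtype=float)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-d (individuals x SNPs)")
    if L == 0:
        return np.empty((G.shape[0], 0))
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; no principal components")
    Gs = Gc[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(Gs, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Gs.shape) * np.finfo(float).eps))
    if L > rank:
        raise ValueError(f"requested L = {L} PCs but the panel has rank {rank}")
    return U[:, :L] * s[:L]
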