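"""Single-layer min-p permutation inference for the MultP-PE statistic.

The raw statistic T_lambda depends on the penalty, and no single lambda is
privileged, so significance is taken as the minimum over the grid of per-
penalty permutation p-values:

    T_MultP-PE = min_lambda p_lambda.

A single layer of B genotype shuffles (Ge et al. style) serves double duty:
the same B permuted statistics provide both the per-lambda reference
distribution

    p_lambda^(b) = #{d in 1..B : T_lambda^(d) < T_lambda^(b)} / B

(low T = significant) and, after taking row-wise minima, the reference
distribution of the min-p statistic itself:

    p = #{b in 1..B : minp^(b) < minp^(0)} / B.

Strict inequality throughout, exactly as the formulas print: ties count as
"not less", so tied statistics can only inflate the p-value, and p = 0 is
possible — downstream reporting renders it as "< 1/B". The permuted rows'
own p-values use the same reference set 1..B, including d = b.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .core import LambdaGrid, build_design, default_grid, loocv_errors_matrix, svd_cache, SVDCache

__all__ = [
    "permute_genotype",
    "per_lambda_pvalues",
    "minp_statistic",
    "overall_pvalue",
    "PermutationResult",
    "multp_pe_test",
    "format_pvalue",
    "snp_rng",
]


def permute_genotype(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniformly random shuffle of the genotype vector."""
    return rng.permutation(np.asarray(x))


def per_lambda_pvalues(T_matrix: np.ndarray,
                       smoothed: bool = False) -> np.ndarray:
    """Rank every T value against the B permuted rows, per penalty column.

    ``T_matrix`` is (B+1) x M with row 0 the observed data. For each column
    the reference set is rows 1..B; each entry's p-value is the fraction of
    reference values strictly below it. Sorting each reference column and
    binary-searching gives the same integer counts as the literal double
    loop in O((B+1) log B).

    With ``smoothed=True`` returns (1 + count) / (1 + B) instead — a valid
    p-value that is never zero; off by default.
    """
    T = np.asarray(T_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2:
        raise ValueError("need a (B+1) x M matrix with B >= 1")
    B = T.shape[0] - 1
    P = np.empty_like(T)
    for m in range(T.shape[1]):
        ref = np.sort(T[1:, m])
        counts = np.searchsorted(ref, T[:, m], side="left")
        P[:, m] = (1 + counts) / (1 + B) if smoothed else counts / B
    return P


def minp_statistic(p_lambda_matrix: np.ndarray) -> np.ndarray:
    """Row-wise minimum over the penalty grid: the min-p statistic per row."""
    P = np.asarray(p_lambda_matrix, dtype=float)
    return P.min(axis=1)


def overall_pvalue(minp: np.ndarray, smoothed: bool = False) -> float:
    """Fraction of permuted min-p values strictly below the observed one."""
    minp = np.asarray(minp, dtype=float)
    B = minp.size - 1
    if B < 1:
        raise ValueError("need at least one permutation")
    count = int(np.sum(minp[1:] < minp[0]))
    return (1 + count) / (1 + B) if smoothed else count / B


def format_pvalue(p: float, B: int) -> str:
    """Render a permutation p-value, using '<1/B' below the resolution."""
    if p == 0.0:
        return f"<{1.0 / B:g}"
    return f"{p:g}"


@dataclass
class PermutationResult:
    """Everything the permutation procedure computed for one variant."""

    T_matrix: np.ndarray          # (B+1) x M, row 0 = observed
    p_lambda_matrix: np.ndarray   # (B+1) x M
    minp: np.ndarray              # length B+1
    p_value: float
    B: int
    seed: object = None

    @property
    def p_value_str(self) -> str:
        return format_pvalue(self.p_value, self.B)


def snp_rng(seed: int, snp_id: str, stage: int = 1) -> np.random.Generator:
    """Deterministic per-SNP random stream.

    Derived from (root seed, crc32 of the SNP identifier, stage) so a scan is
    reproducible regardless of SNP order or chunking, and stage-2 draws are
    independent of stage 1.
    """
    return np.random.default_rng(
        [int(seed), zlib.crc32(str(snp_id).encode()), int(stage)])


#: Permutations are evaluated in blocks of this many columns so that memory
#: stays at ~n * block reals even for very large B.
PERMUTATION_BLOCK = 10_000


def multp_pe_test(phenotypes: np.ndarray,
                  x: np.ndarray,
                  grid: LambdaGrid | None = None,
                  B: int = 1000,
                  rng: np.random.Generator | int | None = None,
                  cache: SVDCache | None = None,
                  smoothed: bool = False) -> PermutationResult:
    """Run the full MultP-PE test of one variant against K phenotypes.

    Builds the intercepted design and its SVD cache once (or reuses a
    supplied ``cache``, e.g. across the SNPs of a scan), stacks the observed
    genotype and B independent shuffles as columns of one n x (B+1) block,
    and obtains all (B+1) x M statistics from a single pass of
    :func:`multppe.core.loocv_errors_matrix`.

    Parameters
    ----------
    phenotypes : n x K matrix (already covariate/PC adjusted if desired).
    x : genotype vector, length n; 0/1/2 counts or residualized reals.
    grid : penalty grid; defaults to log lambda = 0 ... 4.5.
    B : number of permutations.
    rng : numpy Generator, or an int seed, or None for fresh entropy.
    cache : optional precomputed SVD cache for these phenotypes.
    smoothed : use the never-zero (1+count)/(1+B) p-value estimator.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("genotype must be a 1-d vector")
    if np.ptp(x) == 0:
        raise ValueError("monomorphic variant: genotype vector is constant")
    if B < 1:
        raise ValueError("B must be at least 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    elif rng is None:
        rng = np.random.default_rng()

    if cache is None:
        if grid is None:
            grid = default_grid()
        cache = svd_cache(build_design(phenotypes), grid)
    if cache.n != x.size:
        raise ValueError("genotype length does not match the phenotype cache")

    # columns: observed x, then B independent shuffles, evaluated blockwise
    T_matrix = np.empty((B + 1, len(cache.grid)))
    T_matrix[0] = loocv_errors_matrix(cache, x[:, None])[0]
    done = 0
    while done < B:
        nb = min(PERMUTATION_BLOCK, B - done)
        Xb = rng.permuted(np.broadcast_to(x, (nb, x.size)), axis=1).T
        T_matrix[1 + done : 1 + done + nb] = loocv_errors_matrix(cache, Xb)
        done += nb
    P = per_lambda_pvalues(T_matrix, smoothed=smoothed)
    minp = minp_statistic(P)
    p = overall_pvalue(minp, smoothed=smoothed)
    return PermutationResult(T_matrix=T_matrix, p_lambda_matrix=P,
                             minp=minp, p_value=p, B=B, seed=rng)
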