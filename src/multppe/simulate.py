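"""Latent-factor phenotype simulator and type-I-error / power studies.

Phenotypes are generated per individual from

    y = phi * x + c * gamma @ omega + sqrt(1 - c^2) * eps,

where x is the HWE genotype score at the tested variant, phi the length-K
vector of genetic effects, omega an R-variate normal factor vector with unit
variances and pairwise correlation rho (Sigma = rho * J + (1 - rho) * I),
gamma a K x R 0/1 loading matrix assigning each phenotype to exactly one
factor, and eps K independent standard normals. Under the null (beta = 0)
every phenotype is marginal N(0, 1); two phenotypes on the same factor have
correlation c^2, two on different factors rho * c^2.

Four effect/loading configurations are provided:

* model 1 — one factor, effects on all phenotypes with increasing sizes
  (phi = beta * (1, 2, ..., K));
* model 2 — two equal factor blocks, effects (all = beta) on the second
  block only;
* model 3 — five equal blocks; blocks 1-3 null, block 4 constant -beta,
  block 5 increasing 2*beta/(k+1) * (1, ..., k) with k = K/5 (mean +beta);
* model 4 — five blocks; block 1 null, block 2 constant +beta, block 3
  constant -beta, block 4 decreasing negative, block 5 increasing positive.

Defaults follow the type-I-error study conditions: MAF 0.3, within-factor
correlation c^2 = 0.25 and between-factor correlation rho * c^2 = 0.14
(hence c = 0.5, rho = 0.56).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .core import LambdaGrid, default_grid
from .permutation import multp_pe_test

__all__ = [
    "MODEL_FACTORS",
    "SimulationModelSpec",
    "StudyResult",
    "simulate_genotypes",
    "effect_vector",
    "loading_matrix",
    "factor_covariance",
    "simulate_phenotypes",
    "simulate_dataset",
    "type1_study",
    "power_study",
]

#: Number of latent factors R per model id.
MODEL_FACTORS = {1: 1, 2: 2, 3: 5, 4: 5}


@dataclass(frozen=True)
class SimulationModelSpec:
    """Parameters of one simulated study condition."""

    model_id: int
    K: int
    beta: float = 0.0
    c: float = 0.5          # within-factor correlation = c^2
    rho: float = 0.56       # between-factor correlation = rho * c^2
    maf: float = 0.3
    n: int = 1000

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_FACTORS:
            raise ValueError("model_id must be 1, 2, 3 or 4")
        R = self.R
        if self.model_id >= 2 and self.K % R != 0:
            raise ValueError(
                f"model {self.model_id} needs K divisible by {R}, got K={self.K}")
        if not 0 <= self.c**2 < 1:
            raise ValueError("need 0 <= c^2 < 1")
        if not 0 <= self.rho <= 1:
            raise ValueError("need 0 <= rho <= 1")
        if not 0 < self.maf <= 0.5:
            raise ValueError("need 0 < maf <= 0.5")

    @property
    def R(self) -> int:
        return MODEL_FACTORS[self.model_id]

    @classmethod
    def from_correlations(cls, model_id: int, K: int, beta: float = 0.0,
                          within: float = 0.25, between: float = 0.14,
                          maf: float = 0.3, n: int = 1000) -> "SimulationModelSpec":
        """Build a spec from the within/between-factor phenotype correlations."""
        if not 0 < within < 1:
            raise ValueError("within-factor correlation must be in (0, 1)")
        return cls(model_id=model_id, K=K, beta=beta,
                   c=float(np.sqrt(within)), rho=between / within,
                   maf=maf, n=n)


@dataclass(frozen=True)
class StudyResult:
    """Empirical rejection rate of one study cell with its exact binomial CI."""

    replicates: int
    rejections: int
    level: float
    beta: float = 0.0

    @property
    def rate(self) -> float:
        return self.rejections / self.replicates

    @property
    def ci95(self) -> tuple[float, float]:
        ci = binomtest(self.rejections, self.replicates).proportion_ci(
            confidence_level=0.95, method="exact")
        return (ci.low, ci.high)


def simulate_genotypes(maf: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """i.i.d. additive genotype scores under Hardy-Weinberg equilibrium.

    P(0) = (1-p)^2, P(1) = 2p(1-p), P(2) = p^2 for minor allele frequency p.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("need 0 < maf <= 0.5")
    return rng.binomial(2, maf, size=n).astype(float)


def effect_vector(spec: SimulationModelSpec) -> np.ndarray:
    """Genetic effects phi on the K phenotypes for the spec's model."""
    K, beta = spec.K, spec.beta
    if spec.model_id == 1:
        return beta * np.arange(1, K + 1, dtype=float)
    if spec.model_id == 2:
        phi = np.zeros(K)
        phi[K // 2:] = beta
        return phi
    k = K // 5
    ramp = 2 * beta / (k + 1) * np.arange(1, k + 1, dtype=float)
    if spec.model_id == 3:
        return np.concatenate([np.zeros(3 * k), -beta * np.ones(k), ramp])
    # model 4
    return np.concatenate(
        [np.zeros(k), beta * np.ones(k), -beta * np.ones(k), -ramp, ramp])


def loading_matrix(spec: SimulationModelSpec) -> np.ndarray:
    """K x R block-diagonal 0/1 matrix: each phenotype loads on one factor."""
    K, R = spec.K, spec.R
    block = K // R
    gamma = np.zeros((K, R))
    for r in range(R):
        gamma[r * block:(r + 1) * block, r] = 1.0
    return gamma


def factor_covariance(spec: SimulationModelSpec) -> np.ndarray:
    """Sigma = rho * J + (1 - rho) * I for the R latent factors."""
    R = spec.R
    Sigma = spec.rho * np.ones((R, R)) + (1 - spec.rho) * np.eye(R)
    # exchangeable correlation is PD for rho in [0, 1); rho = 1 degenerates
    np.linalg.cholesky(Sigma + 1e-12 * np.eye(R))
    return Sigma


def simulate_phenotypes(spec: SimulationModelSpec, x: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw the n x K phenotype matrix given genotypes x."""
    x = np.asarray(x, dtype=float)
    n = x.size
    phi = effect_vector(spec)
    gamma = loading_matrix(spec)
    L = np.linalg.cholesky(factor_covariance(spec) + 1e-12 * np.eye(spec.R))
    omega = rng.standard_normal((n, spec.R)) @ L.T
    eps = rng.standard_normal((n, spec.K))
    return (x[:, None] * phi[None, :]
            + spec.c * omega @ gamma.T
            + np.sqrt(1 - spec.c**2) * eps)


def simulate_dataset(spec: SimulationModelSpec,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One replicate: genotypes then phenotypes. Returns (Y, x)."""
    x = simulate_genotypes(spec.maf, spec.n, rng)
    return simulate_phenotypes(spec, x, rng), x


def _replicate_pvalue(spec: SimulationModelSpec, B: int,
                      grid: LambdaGrid, seed: int, r: int) -> float:
    # stream (seed, r): replicates are order-independent and resumable
    rng = np.random.default_rng([int(seed), int(r)])
    while True:
        Y, x = simulate_dataset(spec, rng)
        if np.ptp(x) > 0:          # redraw the (tiny-n) monomorphic corner case
            break
    return multp_pe_test(Y, x, grid=grid, B=B, rng=rng).p_value


def type1_study(spec: SimulationModelSpec, replicates: int = 10000,
                B: int = 1000, grid: LambdaGrid | None = None,
                levels: tuple[float, ...] = (0.01, 0.05),
                seed: int = 0) -> list[StudyResult]:
    """Empirical type-I-error rates at each nominal level under the null.

    Each replicate draws fresh genotypes and phenotypes with beta = 0, runs
    the permutation test, and rejects when p < alpha.
    """
    if spec.beta != 0:
        raise ValueError("type-I-error study requires beta = 0")
    if grid is None:
        grid = default_grid()
    rejections = np.zeros(len(levels), dtype=int)
    for r in range(replicates):
        p = _replicate_pvalue(spec, B, grid, seed, r)
        rejections += (p < np.asarray(levels)).astype(int)
    return [StudyResult(replicates=replicates, rejections=int(k),
                        level=a, beta=0.0)
            for k, a in zip(rejections, levels)]


def power_study(spec: SimulationModelSpec, replicates: int = 1000,
                B: int = 1000, grid: LambdaGrid | None = None,
                level: float = 0.05, seed: int = 0) -> StudyResult:
    """Empirical power at one nominal level; at beta = 0 this is type I error."""
    if grid is None:
        grid = default_grid()
    rejections = 0
    for r in range(replicates):
        if _replicate_pvalue(spec, B, grid, seed, r) < level:
            rejections += 1
    return StudyResult(replicates=replicates, rejections=rejections,
                       level=level, beta=spec.beta)
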