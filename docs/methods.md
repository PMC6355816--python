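# Methods

## Model and statistic

MultP-PE tests H₀: β₁ = … = β_K = 0 in the inverse linear model
x_i = y_iᵀβ + ε_i, where x is the additive genotype score at one variant and
y_i = (1, y_i1, …, y_iK)ᵀ stacks an intercept with the K phenotypes. The
ordinal response is treated as numeric; the test's validity rests on the
permutation procedure, not on Gaussian errors, so the 0/1/2 coding (or the
real-valued residual after ancestry adjustment) needs no distributional
assumption. Phenotypes are assumed complete and individuals unrelated;
relatedness would break the exchangeability that genotype shuffling relies
on.

Because correlated phenotypes make YᵀY ill-conditioned, the fit is ridge:
β̂_λ = (YᵀY + λI)⁻¹Yᵀx. The intercept is penalized along with the slopes —
that is what the printed estimator with the ones column inside Y does, and
the package implements it exactly; the intercept shrinkage is absorbed into
the permutation null, so calibration is unaffected. Phenotypes are **not**
standardized before fitting. Ridge is scale-sensitive, so callers with
phenotypes on wildly different scales should z-score them beforehand
(`scipy.stats.zscore` or equivalent); the test itself is invariant under any
fixed preprocessing because the same transformation applies to every
permutation.

The statistic at penalty λ is the LOOCV prediction error
T_λ = Σᵢ (x_i − x̂₋ᵢ^λ)², low values significant. Per-penalty p-values are
combined as T_MultP-PE = min_λ p_λ over a fixed grid.

## Penalty grid

Default: log λ = 0, 1, 2, 3, 3.5, 3.8, 4, 4.5 with the natural logarithm
(λ ≈ 1 … 90). "log" is read as natural log, the unqualified convention in
the statistics literature; the grid is a plain argument everywhere
(`LambdaGrid`, `--lambda-grid`), so a base-10 reading — or any other grid —
is one keyword away. `LambdaGrid.from_lambdas([0, …])` admits λ = 0, which
is useful for recovering the OLS PRESS statistic but is excluded from the
default grid (λ = 0 with n close to K+1 drives leverages to 1, where the
LOOCV identity degenerates).

## Fast path and numerical guards

From the thin SVD Y = UDVᵀ (exactly K+1 components, requiring n ≥ K+1; fewer
individuals than coefficients is an error instructing the caller to reduce
K, not a silently different estimator):

* shrinkage c_λ,j = d_j²/(d_j² + λ), cached as a (K+1) × M matrix C;
* leverages h_λ = diag(U C_λ Uᵀ), cached as an n × M matrix H;
* for any genotype block X (observed column plus permutations),
  x̂ = U(C ∗ Uᵀx) and T = colSum(Q ∗ Q) with Q = (X − X̂)/(1 − H),
  ∗ and / element-wise.

U, C, H depend only on the phenotypes and the grid, so one decomposition
serves every permutation and every SNP of a scan (an instrumented counter in
`gwas_scan` asserts this). Per-SNP missing genotypes break the sharing; the
affected SNP is re-analyzed on its complete subsample with a rebuilt cache
(logged) rather than imputed.

Guards: division by 1 − h uses ε = 10⁻¹⁰; any leverage above 1 − ε raises an
error naming the offending rows instead of clamping, since such a row means
the leave-one-out problem is degenerate. d_j = 0 with λ = 0 defines
c = 0 (the component is absent). Permutations are evaluated in blocks of
10,000 columns, so memory stays at ~n × 10⁴ doubles regardless of B; the
statistic matrix itself is only (B+1) × M.

The blocked path and a per-permutation loop agree to 10⁻¹² relative
tolerance rather than bit-for-bit: BLAS matrix products use different
accumulation orders for 1-column and many-column operands. The brute-force
equivalence that matters scientifically — SVD fast path vs explicit n-fold
refitting — holds at ~10⁻¹⁵ relative and is asserted at 10⁻⁸.

## Permutation inference

With B shuffles of the genotype vector (phenotype rows fixed), indexing the
observed data as b = 0:

    p_λ^(b) = #{d ∈ 1..B : T_λ^(d) < T_λ^(b)} / B
    p       = #{b ∈ 1..B : min_λ p_λ^(b) < min_λ p_λ^(0)} / B

Choices pinned by the brute-force oracle test: the reference set is always
d = 1..B (a permuted row is compared against the set including itself);
inequalities are strict, so ties count as "not less" and can only inflate
p-values (conservative); p = 0 is possible and is reported as "< 1/B". An
optional `smoothed=True` mode returns (1 + count)/(1 + B) for users who need
a never-zero valid p-value; it is off by default because the strict-count
estimator is the definition the rest of the package (and its calibration
results) uses. The sort-and-binary-search implementation produces the same
integer counts as the literal double loop, in O((B+1) log B) per penalty.

Rejection at level α in the study drivers means p < α: p-values live on the
lattice {0, 1/B, …}, and with B = 1,000, P(p < 0.05) under a uniform rank is
exactly 50/1000 = 0.05.

## Two-stage screening

Genome-wide scans use a cheap pass at stage1_B = 1,000 permutations on every
SNP, then stage2_B permutations only on SNPs with stage-1 p ≤ 0.005. The
stage-2 default is 10⁶ — large enough to order candidate loci while staying
desk-friendly; genome-wide significance claims at 5 × 10⁻⁸ need B ≈ 10⁸,
which the same code path handles given the hours it deserves. Stage-2 draws
are fresh, independent of stage 1 (per-SNP stream seeded by
(root seed, crc32(snp id), stage)), so selection does not bias the stage-2
p-value conditional on selection, and results are reproducible under any SNP
ordering or chunking.

## Adjustment

Covariates: each phenotype is replaced by its OLS residual on an intercept
plus the covariates (residualization is idempotent and leaves the test
invariant to adding any linear combination of covariates to a phenotype).
Population stratification: genotype *and* phenotypes are replaced by
residuals on the top L ancestry PCs (default L = 10). PCs are computed from
a background genotype panel with each SNP column centered and scaled to unit
variance — the standard ancestry-PC convention; scores are left singular
vectors times singular values. When both adjustments are requested,
covariates are applied first, then PCs. Missing phenotype/covariate/PC
values drop the individual listwise; missing genotypes drop the individual
for that SNP only.

## Simulator

Phenotypes: y = φx + cγω + √(1−c²)·ε with ω ~ MVN(0, ρJ + (1−ρ)I) over R
factors, γ a 0/1 block-diagonal loading matrix (each phenotype loads on
exactly one factor), ε independent standard normals. Under the null each
phenotype is marginal N(0,1); within-factor correlation is c², between-factor
ρc². Genotypes are i.i.d. HWE draws at a given MAF (equivalently
Binomial(2, maf)). Four effect configurations (models 1–4) range from
homogeneous effects on one factor to opposite-signed effects across four of
five factors.

Defaults are the type-I-error study conditions: MAF 0.3, within-factor
correlation 0.25, between-factor correlation 0.14 (c = 0.5, ρ = 0.56). The
power-figure settings quote a between-factor correlation of 0.15 instead;
both are one constructor argument
(`SimulationModelSpec.from_correlations(..., between=0.15)`). Replicate r of
a study uses the stream (seed, r), so studies are resumable and
order-independent.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs, non-Gaussian or heteroskedastic phenotypes, relatedness, genotyping
error, or missingness patterns. Passing the calibration and power tests
therefore demonstrates correctness of the method under its own generative
assumptions, not robustness of those assumptions to real cohort data.

## Problem sizes used in the shipped tests

The test suite runs the statistical checks at sizes chosen to give
conclusive Monte-Carlo evidence in a few minutes: type-I calibration at
1,000 replicates × B = 1,000 (n = 500, K = 10; exact binomial 95% CI must
cover the nominal level), power monotonicity at 200 replicates per (model,
β) point (n = 1,000, K = 20, B = 500), stratification at 150 replicates
(n = 400, B = 300), and simulator correlation structure at n = 200,000
(±0.01). Full-scale studies (10,000 replicates, B = 1,000) run through the
same `type1_study` code path in a few hours of CPU.

## Known limitations

* Permutation cost scales linearly in B; there is no analytic or
  importance-sampling approximation for extreme p-values.
* The min-p statistic's resolution is 1/B at every layer, so stage-2 budgets
  bound the smallest reportable p-value.
* n must exceed K+1; very high-dimensional phenotype panels need dimension
  reduction upstream.
* PC adjustment assumes the background panel captures the confounding axes;
  family structure needs mixed-model machinery that is out of scope here.
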