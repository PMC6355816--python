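"""Per-SNP genome-wide scan driver with two-stage permutation screening.

The expensive parts of the MultP-PE permutation test — the design SVD, the
shrinkage factors and the leverages — depend only on the (adjusted)
phenotypes, so a scan builds them once and reuses them for every SNP and
every permutation. Screening is two-stage: a cheap pass (default B = 1,000)
over all SNPs, then a high-resolution pass (default B = 10^6; raise it for
genome-wide significance claims) only on SNPs whose stage-1 p-value clears
the selection threshold (default 0.005).

Per-SNP missing genotypes are handled by dropping those individuals for that
SNP only; this breaks the shared-cache economy for that SNP, so the cache is
rebuilt on the subsample (logged) rather than imputing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .adjust import residualize, residualize_for_stratification
from .core import LambdaGrid, build_design, default_grid, svd_cache
from .io import GenotypePanel
from .permutation import multp_pe_test, snp_rng

logger = logging.getLogger("multppe")

__all__ = ["SnpRecord", "ScanResult", "gwas_scan"]

#: Conventional genome-wide significance threshold used for flagging.
GENOME_WIDE_ALPHA = 5e-8


@dataclass
class SnpRecord:
    snp_id: str
    n_used: int
    stage1_p: float
    selected: bool
    stage2_p: float | None = None


@dataclass
class ScanResult:
    records: list[SnpRecord]
    stage1_B: int
    stage2_B: int
    n_svd_builds: int = 0      # cache-economy instrumentation

    def as_dict(self) -> dict[str, SnpRecord]:
        return {r.snp_id: r for r in self.records}


def _aligned(panel: GenotypePanel, phenotypes, covariates, pcs):
    """Intersect individual IDs across all inputs; listwise-delete rows with
    any missing phenotype/covariate/PC value (per-SNP genotype missingness is
    handled downstream)."""
    import pandas as pd

    ids = pd.Index(panel.individual_ids)
    tables = {"phenotypes": phenotypes}
    if covariates is not None:
        tables["covariates"] = covariates
    if pcs is not None:
        tables["pcs"] = pcs
    for name, t in tables.items():
        ids = ids.intersection(t.index)
    if len(ids) == 0:
        raise ValueError("no individuals shared by genotypes and phenotypes")
    # order-normalize to the panel's order
    ids = pd.Index([i for i in panel.individual_ids if i in set(ids)])
    complete = np.ones(len(ids), dtype=bool)
    for t in tables.values():
        complete &= ~t.loc[ids].isna().any(axis=1).to_numpy()
    ids = ids[complete]
    if len(ids) == 0:
        raise ValueError("listwise deletion removed every individual")
    out = {name: t.loc[ids].to_numpy(dtype=float) for name, t in tables.items()}
    return ids, out


def gwas_scan(panel: GenotypePanel, phenotypes, covariates=None, pcs=None,
              grid: LambdaGrid | None = None, stage1_B: int = 1000,
              stage1_threshold: float = 0.005, stage2_B: int = 10**6,
              seed: int = 0) -> ScanResult:
    """Run the two-stage MultP-PE scan over every SNP of a panel.

    Parameters
    ----------
    panel : GenotypePanel from :func:`multppe.io.read_genotypes`.
    phenotypes, covariates, pcs : pandas DataFrames indexed by individual ID.
    grid : penalty grid (default log lambda = 0 ... 4.5).
    stage1_B, stage1_threshold, stage2_B : screening parameters; SNPs with
        stage-1 p <= threshold are retested at stage2_B permutations.
    seed : root seed; each SNP and stage uses an independent derived stream,
        so results do not depend on SNP order or chunking.
    """
    if grid is None:
        grid = default_grid()
    ids, data = _aligned(panel, phenotypes, covariates, pcs)
    Y = data["phenotypes"]
    if covariates is not None:
        Y = residualize(Y, data["covariates"])
    pc_values = data.get("pcs")
    if pc_values is not None:
        Y = residualize(Y, pc_values)

    geno = panel.genotypes.loc[ids]
    n_svd = 0
    full_cache = svd_cache(build_design(Y), grid)
    n_svd += 1

    def test_one(snp_id: str, B: int, stage: int):
        g = geno[snp_id].to_numpy(dtype=float)
        mask = ~np.isnan(g)
        rng = snp_rng(seed, snp_id, stage)
        nonlocal n_svd
        if mask.all():
            x = g
            Ys, cache = Y, full_cache
        else:
            logger.info("SNP %s: %d missing genotypes, rebuilding cache "
                        "on the subsample", snp_id, int((~mask).sum()))
            x, Ys = g[mask], Y[mask]
            cache = svd_cache(build_design(Ys), grid)
            n_svd += 1
        if np.ptp(x) == 0:
            return None, int(mask.sum())
        if pc_values is not None:
            _, x = residualize_for_stratification(Ys, x, pc_values[mask])
            if np.ptp(x) < 1e-12:   # variant fully explained by ancestry PCs
                return None, int(mask.sum())
        res = multp_pe_test(Ys, x, B=B, rng=rng, cache=cache)
        return res.p_value, int(mask.sum())

    records: list[SnpRecord] = []
    any_polymorphic = False
    for snp_id in panel.snp_ids:
        p1, n_used = test_one(snp_id, stage1_B, stage=1)
        if p1 is None:
            logger.warning("SNP %s is monomorphic in the analysis sample; "
                           "skipped", snp_id)
            records.append(SnpRecord(snp_id, n_used, float("nan"), False))
            continue
        any_polymorphic = True
        selected = p1 <= stage1_threshold
        rec = SnpRecord(snp_id, n_used, p1, selected)
        if selected:
            rec.stage2_p, _ = test_one(snp_id, stage2_B, stage=2)
            if rec.stage2_p is not None and rec.stage2_p < GENOME_WIDE_ALPHA:
                logger.info("SNP %s below genome-wide threshold %g",
                            snp_id, GENOME_WIDE_ALPHA)
        records.append(rec)
    if not any_polymorphic:
        raise ValueError("all SNPs are monomorphic in the analysis sample")
    return ScanResult(records=records, stage1_B=stage1_B, stage2_B=stage2_B,
                      n_svd_builds=n_svd)
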