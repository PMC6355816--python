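"""File ingestion and result serialization for genome-wide scans.

Two text genotype layouts are supported:

* ``plink-raw`` — the PLINK ``--recode A`` dialect: whitespace-separated,
  header ``FID IID PAT MAT SEX PHENOTYPE <SNP>_<allele> ...``, additive
  dosages 0/1/2 or NA;
* ``tsv`` — a plain tab-separated table, first column individual IDs,
  remaining columns one SNP each, same value alphabet.

On ingestion every SNP is oriented to count the minor allele: if the coded
allele's frequency exceeds 0.5 the scores are flipped to ``2 - g`` and the
flip recorded on the panel. Phenotype / covariate / PC tables are TSV with
a header row and the individual ID in the first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("multppe")

__all__ = [
    "GenotypePanel",
    "read_genotypes",
    "read_table",
    "write_results",
    "read_results",
]

_RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypePanel:
    """n individuals x S SNPs of additive genotype scores (NaN = missing)."""

    genotypes: pd.DataFrame           # index: individual IDs, columns: SNP ids
    flipped: dict = field(default_factory=dict)  # snp_id -> coded-allele freq

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.genotypes.shape


def _orient_minor(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Flip SNP columns whose coded-allele frequency exceeds one half."""
    flipped = {}
    freq = df.mean(axis=0, skipna=True) / 2.0
    for snp in df.columns[freq.to_numpy() > 0.5]:
        flipped[snp] = float(freq[snp])
        df[snp] = 2.0 - df[snp]
        logger.info("flipped %s to minor-allele coding (coded freq %.3f)",
                    snp, flipped[snp])
    return df, flipped


def _validate_scores(df: pd.DataFrame, path) -> None:
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: genotype value {vals[i, j]!r} at individual "
            f"{df.index[i]!r}, SNP {df.columns[j]!r} is not 0/1/2/NA")


def read_genotypes(path, format: str = "tsv") -> GenotypePanel:
    """Read a genotype panel from ``plink-raw`` or plain ``tsv`` text."""
    if format == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing = [c for c in _RAW_META_COLS if c not in df.columns[:6]]
        if missing:
            raise ValueError(
                f"{path}: malformed .raw header, missing columns {missing}")
        ids = df["FID"].astype(str) + "_" + df["IID"].astype(str)
        # strip the trailing _<allele> tag from SNP column names
        snps = df.columns[6:]
        geno = df[snps].replace("NA", np.nan).astype(float)
        geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in snps]
        geno.index = ids
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        geno = df.iloc[:, 1:].replace("NA", np.nan).astype(float)
        geno.index = df.iloc[:, 0].astype(str)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if geno.index.duplicated().any():
        dup = geno.index[geno.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate individual ID {dup!r}")
    if pd.Index(geno.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate SNP identifiers")
    _validate_scores(geno, path)
    geno, flipped = _orient_minor(geno)
    return GenotypePanel(genotypes=geno, flipped=flipped)


def read_table(path) -> pd.DataFrame:
    """TSV with header and individual-ID first column -> float DataFrame."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df.astype(float)


def write_results(result, path) -> None:
    """Serialize a ScanResult to TSV.

    Sub-resolution p-values (permutation count zero) are written as the
    literal ``<1/B``; SNPs not selected for stage 2 leave that cell empty.
    """
    from .permutation import format_pvalue

    rows = []
    for rec in result.records:
        stage1 = (format_pvalue(rec.stage1_p, result.stage1_B)
                  if np.isfinite(rec.stage1_p) else "NA")
        stage2 = ""
        if rec.selected and rec.stage2_p is not None:
            stage2 = format_pvalue(rec.stage2_p, result.stage2_B)
        rows.append({"snp_id": rec.snp_id, "n_used": rec.n_used,
                     "stage1_p": stage1, "selected": int(rec.selected),
                     "stage2_p": stage2})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` output."""
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "stage1_p": str,
                                              "stage2_p": str},
                       keep_default_na=False)
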