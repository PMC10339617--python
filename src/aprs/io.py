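"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
* Genotypes: VCF (one record per variant, ``GT`` fields) read through
  ``cyvcf2``, or a tab-delimited dosage matrix (rows = samples, header row of
  variant ids).
* Scoring file: PGS-Catalog dialect — ``#``-prefixed header lines, then
  tab-separated ``rsID, chr_name, chr_position, effect_allele, other_allele,
  effect_weight``.
* Covariates / phenotypes: one row per sample, tab-delimited.
* Relatedness: ``id1  id2  kinship`` triples, tab-delimited.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenotypeSet, ScoringFile

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_matrix",
    "read_dosage_matrix",
    "write_scoring_file",
    "write_covariates",
    "read_covariates",
    "write_kinship_pairs",
    "read_kinship_pairs",
]

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(genotypes: GenotypeSet, path: str | os.PathLike) -> None:
    """Write hard-call genotypes as an uncompressed VCF.

    Dosages are rounded to the nearest integer genotype; missing dosages are
    written as ``./.``.
    """
    variants = genotypes.variants
    contigs = []
    for c in variants["chrom"]:
        if c not in contigs:
            contigs.append(c)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        dos = genotypes.dosages
        for j, row in enumerate(variants.itertuples(index=False)):
            calls = []
            for d in dos[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(gt_strings[int(round(d))])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t"
                f"{row.alt}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | os.PathLike) -> GenotypeSet:
    """Read a VCF into a :class:`GenotypeSet` of alt-allele dosages."""
    from cyvcf2 import VCF  # deferred: htslib import is comparatively slow

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    meta: list[tuple] = []
    rows: list[np.ndarray] = []
    # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    dose_of = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        meta.append((v.ID, v.CHROM, v.POS, v.REF, alt))
        rows.append(dose_of[v.gt_types])
    vcf.close()
    if not meta:
        raise ValueError(f"no variant records in {path}")
    variants = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    return GenotypeSet(
        samples=samples, variants=variants, dosages=np.column_stack(rows)
    )


def write_dosage_matrix(genotypes: GenotypeSet, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.samples, name="sample_id"),
        columns=genotypes.variants["variant_id"].to_numpy(),
    )
    df.to_csv(path, sep="\t", float_format="%g")


def read_dosage_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dosage matrix; variant metadata must come from elsewhere."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_scoring_file(scoring: ScoringFile, path: str | os.PathLike) -> None:
    """Write a scoring file in the PGS-Catalog text dialect."""
    with open(path, "w") as fh:
        if scoring.pgs_id:
            fh.write(f"#pgs_id={scoring.pgs_id}\n")
        fh.write("#genome_build=NR\n")
        fh.write(
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\t"
            "effect_weight\n"
        )
        for r in scoring.records.itertuples(index=False):
            fh.write(
                f"{r.variant_id}\t{r.chrom}\t{r.pos}\t{r.effect_allele}\t"
                f"{r.other_allele}\t{r.effect_weight:.10g}\n"
            )


def write_covariates(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_kinship_pairs(
    pairs: pd.DataFrame, path: str | os.PathLike
) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_kinship_pairs(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["id1", "id2", "kinship"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"kinship file must have columns {expected}")
    return df
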