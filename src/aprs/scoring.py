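"""Polygenic risk scoring: parse published weights, harmonize, score, z-score.

The score of sample *i* is the canonical weighted sum
``PRS_i = sum_j w_j * d_ij`` over the variants of a published scoring file,
where ``d_ij`` is the dosage of the listed effect allele.  Harmonization
reconciles the scoring file's allele orientation with the genotype data:
strand-ambiguous records (A/T or C/G pairs) are excluded outright, matching
records are used as-is, allele-swapped records have their dosage flipped
(``d -> 2 - d``), and records matching only after strand complement are
complemented first.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SCORING_COLUMNS, GenotypeSet, ScoringFile

__all__ = [
    "read_scoring_file",
    "harmonize",
    "compute_prs",
    "standardize",
    "HarmonizationResult",
]

_COLUMN_ALIASES = {
    "rsid": "variant_id",
    "rsID": "variant_id",
    "variant_id": "variant_id",
    "chr_name": "chrom",
    "chrom": "chrom",
    "chr_position": "pos",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "reference_allele": "other_allele",
    "effect_weight": "effect_weight",
    "beta": "effect_weight",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def read_scoring_file(path: str | os.PathLike) -> ScoringFile:
    """Parse a PGS-Catalog-dialect scoring file.

    ``#``-prefixed header lines are skipped (a ``#pgs_id=`` line, if present,
    is kept as metadata); column aliases such as ``rsID``/``rsid`` and
    ``beta``/``effect_weight`` are accepted.
    """
    pgs_id = None
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line[1:].strip().lower().startswith("pgs_id="):
                pgs_id = line.split("=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype={"chr_name": str})
    renames = {}
    for col in df.columns:
        key = col if col in _COLUMN_ALIASES else col.lower()
        if key in _COLUMN_ALIASES:
            renames[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=renames)
    missing = [c for c in SCORING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"scoring file {path} lacks mandatory column(s): {missing}"
        )
    weights = pd.to_numeric(df["effect_weight"], errors="coerce")
    bad = weights.isna() & df["effect_weight"].notna()
    if bad.any():
        # +2 for the column-header line and 1-based numbering
        lineno = int(bad.idxmax()) + header_lines + 2
        raise ValueError(
            f"non-numeric effect weight at line {lineno} of {path}"
        )
    df["effect_weight"] = weights
    df["chrom"] = df["chrom"].astype(str)
    return ScoringFile(records=df[SCORING_COLUMNS].copy(), pgs_id=pgs_id)


@dataclass
class HarmonizationResult:
    """Matched scoring records aligned to genotype columns, plus a report.

    ``matched`` columns: ``variant_id``, ``genotype_index`` (column in the
    dosage matrix), ``effect_weight``, ``flip`` (True when the effect-allele
    dosage is ``2 - d``), ``complemented``.
    """

    matched: pd.DataFrame
    report: dict[str, int] = field(default_factory=dict)


def _classify(effect: str, other: str, ref: str, alt: str) -> tuple[str, bool, bool]:
    """Classify one scoring record against a genotype variant.

    Returns (category, flip, complemented) with category in
    {ambiguous, match, flip, complement, complement_flip, unmatched}.
    """
    if _COMPLEMENT[effect] == other:
        return "ambiguous", False, False
    if effect == alt and other == ref:
        return "match", False, False
    if effect == ref and other == alt:
        return "flip", True, False
    ce, co = _COMPLEMENT[effect], _COMPLEMENT[other]
    if ce == alt and co == ref:
        return "complement", False, True
    if ce == ref and co == alt:
        return "complement_flip", True, True
    return "unmatched", False, False


def harmonize(
    scoring: ScoringFile, genotypes: GenotypeSet
) -> HarmonizationResult:
    """Match scoring records to genotype variants, resolving allele orientation.

    Records are matched by variant id first, then by chrom+pos.  Ambiguous
    records are excluded; orientation is resolved per the module docstring;
    records whose alleles cannot be reconciled are dropped and counted.
    Raises if no record survives.
    """
    gv = genotypes.variants
    by_id = {v: i for i, v in enumerate(gv["variant_id"])}
    by_pos = {(c, p): i for i, (c, p) in enumerate(zip(gv["chrom"], gv["pos"]))}
    report = {
        k: 0
        for k in (
            "matched",
            "flipped",
            "complemented",
            "ambiguous_excluded",
            "unmatched",
            "not_in_genotypes",
        )
    }
    rows = []
    for rec in scoring.records.itertuples(index=False):
        idx = by_id.get(rec.variant_id)
        if idx is None:
            idx = by_pos.get((str(rec.chrom), rec.pos))
        if idx is None:
            report["not_in_genotypes"] += 1
            continue
        category, flip, comp = _classify(
            rec.effect_allele, rec.other_allele, gv["ref"].iat[idx], gv["alt"].iat[idx]
        )
        if category == "ambiguous":
            report["ambiguous_excluded"] += 1
            continue
        if category == "unmatched":
            report["unmatched"] += 1
            continue
        report["matched"] += 1
        if flip:
            report["flipped"] += 1
        if comp:
            report["complemented"] += 1
        rows.append((rec.variant_id, idx, rec.effect_weight, flip, comp))
    if not rows:
        raise ValueError("no scoring record could be matched to the genotypes")
    matched = pd.DataFrame(
        rows,
        columns=["variant_id", "genotype_index", "effect_weight", "flip", "complemented"],
    )
    return HarmonizationResult(matched=matched, report=report)


def compute_prs(
    harmonized: HarmonizationResult, genotypes: GenotypeSet
) -> pd.Series:
    """Raw PRS per sample: the weighted effect-allele dosage sum.

    Missing dosages are imputed with the variant's cohort mean effect-allele
    dosage (``2 * frequency``); a variant with every dosage missing is
    dropped (recorded in the report).
    """
    m = harmonized.matched
    if len(m) == 0:
        raise ValueError("no matched variants to score")
    idx = m["genotype_index"].to_numpy()
    d = genotypes.dosages[:, idx].copy()
    flip = m["flip"].to_numpy()
    d[:, flip] = 2.0 - d[:, flip]
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        harmonized.report["dropped_all_missing"] = int(all_missing.sum())
        d = d[:, ~all_missing]
        w = m.loc[~all_missing, "effect_weight"].to_numpy()
    else:
        w = m["effect_weight"].to_numpy()
    col_mean = np.nanmean(d, axis=0)
    miss = np.isnan(d)
    if miss.any():
        d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return pd.Series(d @ w, index=pd.Index(genotypes.samples, name="sample_id"), name="prs_raw")


def standardize(scores) -> np.ndarray:
    """Z-score with the cohort mean and population (divide-by-n) SD."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate score distribution (zero variance)")
    return (x - x.mean()) / sd
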