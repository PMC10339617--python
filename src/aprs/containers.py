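"""Core in-memory containers shared across the pipeline.

Two structured containers are defined here: :class:`GenotypeSet` (sample x
variant alt-allele dosages with variant metadata) and :class:`ScoringFile`
(published per-variant effect weights).  Tabular per-sample data — covariates,
phenotypes, risk scores — travel as plain :class:`pandas.DataFrame` objects
with documented column conventions (see :mod:`aprs.simulate` and
:mod:`aprs.io`): wrapping a DataFrame would only hide the API users already
know.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeSet", "ScoringFile", "VALID_ALLELES"]

VALID_ALLELES = frozenset("ACGT")

#: columns of the variant-metadata frame of a GenotypeSet
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]

#: columns of the records frame of a ScoringFile
SCORING_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "effect_weight",
]


@dataclass
class GenotypeSet:
    """Sample x variant alt-allele dosage matrix with variant metadata.

    Parameters
    ----------
    samples
        Sample identifiers, length ``n``.
    variants
        Frame with columns ``variant_id, chrom, pos, ref, alt``; ``m`` rows.
    dosages
        ``(n, m)`` float array of alt-allele counts in ``[0, 2]``; ``nan``
        marks a missing genotype.
    populations
        Optional per-sample population labels (ground truth in simulations,
        assigned ancestry otherwise).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(
                f"{len(self.samples)} sample ids for {n} dosage rows"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"{len(self.variants)} variant records for {m} dosage columns"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata lacks columns: {missing}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        if self.populations is not None:
            self.populations = np.asarray(self.populations)
            if len(self.populations) != n:
                raise ValueError("population labels must match sample count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_frequencies(self) -> np.ndarray:
        """Per-variant alt-allele frequency (missing dosages ignored)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, index: np.ndarray) -> "GenotypeSet":
        index = np.asarray(index)
        return GenotypeSet(
            samples=[self.samples[i] for i in index],
            variants=self.variants,
            dosages=self.dosages[index],
            populations=None if self.populations is None else self.populations[index],
        )


@dataclass
class ScoringFile:
    """Published per-variant effect alleles and weights (PGS-Catalog style)."""

    records: pd.DataFrame = field(repr=False)
    pgs_id: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SCORING_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"scoring records lack columns: {missing}")
        dup = self.records["variant_id"][self.records["variant_id"].duplicated()]
        if len(dup):
            raise ValueError(
                "duplicate variant ids in scoring file: "
                + ", ".join(map(str, dup.unique()[:5]))
            )
        for col in ("effect_allele", "other_allele"):
            bad = ~self.records[col].isin(list(VALID_ALLELES))
            if bad.any():
                raise ValueError(
                    f"non-ACGT allele in column {col}: "
                    f"{self.records.loc[bad, col].unique()[:5]}"
                )
        w = self.records["effect_weight"]
        if not np.isfinite(w.to_numpy(dtype=float)).all():
            raise ValueError("non-finite effect weight in scoring file")

    def __len__(self) -> int:
        return len(self.records)

    def is_ambiguous(self) -> np.ndarray:
        """Boolean mask of strand-ambiguous records (A/T or C/G pairs)."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        eff = self.records["effect_allele"].to_numpy()
        oth = self.records["other_allele"].to_numpy()
        return np.array([comp[e] == o for e, o in zip(eff, oth)])
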