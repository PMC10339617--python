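"""Cohort derivation: diagnosis-code mapping, BMI rule, QC, relatedness pruning.

Case status is derived from long-format diagnosis records (one row per
sample/system/code) against disease code sets given as patterns:

* ``"I24.1"`` — one concrete code;
* ``"I21.X"`` — prefix wildcard: matches ``I21`` and any subcode of it;
* ``"K40.[1-4]"`` — bracketed range, expanding to ``K40.1 … K40.4``
  (en-dash or hyphen accepted).

Codes are compared dot-insensitively (biobank extracts store ``I211`` for
``I21.1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "CodeSet",
    "expand_code_pattern",
    "derive_case_status",
    "derive_obesity",
    "apply_qc_filters",
    "prune_relatedness",
    "DEFAULT_CODESETS",
    "QC_FLAG_COLUMNS",
    "DEFAULT_KINSHIP_THRESHOLD",
]

CODE_SYSTEMS = ("ICD10", "ICD9", "OPCS4", "SELF")

QC_FLAG_COLUMNS = (
    "qc_sex_discordant",
    "qc_aneuploidy",
    "qc_het_missing_outlier",
)

#: kinship above this flags second-degree-or-closer relatives
DEFAULT_KINSHIP_THRESHOLD = 0.0884

_BRACKET_RE = re.compile(r"^(?P<stem>.+)\[(?P<lo>\d+)[–-](?P<hi>\d+)\]$")


@dataclass(frozen=True)
class CodeSet:
    """Diagnosis/procedure/self-report code patterns defining one disease."""

    icd10: tuple[str, ...] = ()
    icd9: tuple[str, ...] = ()
    opcs4: tuple[str, ...] = ()
    self_report: tuple[int, ...] = ()

    def patterns_for(self, system: str) -> tuple:
        return {
            "ICD10": self.icd10,
            "ICD9": self.icd9,
            "OPCS4": self.opcs4,
            "SELF": tuple(str(c) for c in self.self_report),
        }[system]


# Disease definitions: CAD by ICD-10/ICD-9/OPCS-4/self-report, T2D by ICD-10
# E11.X and self-report 1223.  Obesity is BMI-based (derive_obesity).
DEFAULT_CODESETS: dict[str, CodeSet] = {
    "cad": CodeSet(
        icd10=("I21.X", "I22.X", "I23.X", "I24.1", "I25.2"),
        icd9=("410.X", "411.0", "412.X", "429.79"),
        opcs4=(
            "K40.[1-4]",
            "K41.[1-4]",
            "K45.[1-5]",
            "K49.[1-2]",
            "K49.[8-9]",
            "K50.2",
            "K75.[1-4]",
            "K75.[8-9]",
        ),
        self_report=(1075,),
    ),
    "t2d": CodeSet(icd10=("E11.X",), self_report=(1223,)),
}


def _normalize(code: str) -> str:
    return str(code).replace(".", "").upper().strip()


def expand_code_pattern(pattern: str) -> list[str]:
    """Expand one pattern into concrete codes and/or prefix markers.

    Returns a list whose elements are either concrete codes or strings of the
    form ``"prefix*"`` (trailing star marks a prefix matcher, produced by the
    ``.X`` wildcard).
    """
    pattern = pattern.strip()
    m = _BRACKET_RE.match(pattern)
    if m:
        stem, lo, hi = m.group("stem"), m.group("lo"), m.group("hi")
        if len(lo) != len(hi) or int(lo) > int(hi):
            raise ValueError(f"malformed bracket range in pattern {pattern!r}")
        return [f"{stem}{v}" for v in range(int(lo), int(hi) + 1)]
    if "[" in pattern or "]" in pattern:
        raise ValueError(f"malformed bracket range in pattern {pattern!r}")
    if pattern.endswith(".X"):
        return [pattern[:-2] + "*"]
    return [pattern]


def _matchers(patterns: tuple) -> tuple[set[str], tuple[str, ...]]:
    """Split expanded patterns into exact codes and prefix stems (normalized)."""
    exact: set[str] = set()
    prefixes: list[str] = []
    for pat in patterns:
        for item in expand_code_pattern(pat):
            if item.endswith("*"):
                prefixes.append(_normalize(item[:-1]))
            else:
                exact.add(_normalize(item))
    return exact, tuple(prefixes)


def _code_matches(code: str, exact: set[str], prefixes: tuple[str, ...]) -> bool:
    code = _normalize(code)
    return code in exact or any(code.startswith(p) for p in prefixes)


def derive_case_status(
    records: pd.DataFrame, codeset: CodeSet, sample_ids: list[str] | None = None
) -> pd.Series:
    """Case indicator per sample from long-format diagnosis records.

    ``records`` needs columns ``sample_id, system, code``; a sample is a case
    iff any of its records matches any pattern of its code system.  Samples
    listed in ``sample_ids`` but absent from the records are controls.
    """
    unknown = set(records["system"]) - set(CODE_SYSTEMS)
    if unknown:
        raise ValueError(f"unknown code system tag(s): {sorted(unknown)}")
    matchers = {s: _matchers(codeset.patterns_for(s)) for s in CODE_SYSTEMS}
    hit = records.apply(
        lambda r: _code_matches(r["code"], *matchers[r["system"]]), axis=1
    )
    cases = set(records.loc[hit.to_numpy(dtype=bool), "sample_id"]) if len(records) else set()
    if sample_ids is None:
        sample_ids = list(pd.unique(records["sample_id"]))
    return pd.Series(
        [1 if s in cases else 0 for s in sample_ids],
        index=pd.Index(sample_ids, name="sample_id"),
        name="case",
    )


def derive_obesity(bmi) -> pd.Series | float:
    """Obesity indicator: 1 iff BMI strictly greater than 25 kg/m².

    Missing BMI propagates as NaN — such samples are excluded from the
    obesity analysis rather than coded as controls.
    """
    arr = pd.Series(np.atleast_1d(np.asarray(bmi, dtype=float)))
    if ((arr <= 0) & arr.notna()).any():
        raise ValueError("BMI must be positive")
    out = pd.Series(np.where(arr.isna(), np.nan, (arr > 25.0).astype(float)))
    if np.isscalar(bmi) or np.ndim(bmi) == 0:
        return float(out.iloc[0])
    return out


def apply_qc_filters(
    table: pd.DataFrame, flag_columns: tuple[str, ...] = QC_FLAG_COLUMNS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop samples with any QC flag set; log counts per reason.

    A sample flagged in several columns is removed once but counted under
    every reason.
    """
    missing = [c for c in flag_columns if c not in table.columns]
    if missing:
        raise ValueError(f"QC flag column(s) missing: {missing}")
    log = {c: int((table[c] == 1).sum()) for c in flag_columns}
    keep = ~(table[list(flag_columns)] == 1).any(axis=1)
    log["removed_total"] = int((~keep).sum())
    return table.loc[keep].reset_index(drop=True), log


def prune_relatedness(
    table: pd.DataFrame,
    pairs: pd.DataFrame,
    threshold: float = DEFAULT_KINSHIP_THRESHOLD,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove samples until no pair with kinship above ``threshold`` remains.

    From each related pair one member is retained at random (seeded).  In
    components larger than a pair the highest-degree sample is removed
    iteratively, ties broken by the seeded RNG — this yields an independent
    set.  Node order is canonicalized by sample id so the outcome does not
    depend on input row order.  Pairs referencing unknown ids are skipped
    with a warning entry in the returned log.
    """
    ids = set(table["sample_id"])
    log: list[str] = []
    graph = nx.Graph()
    for r in pairs.itertuples(index=False):
        a, b, k = str(r.id1), str(r.id2), float(r.kinship)
        if a not in ids or b not in ids:
            log.append(f"warning: pair ({a}, {b}) references unknown id; skipped")
            continue
        if k > threshold:
            graph.add_edge(a, b)
    rng = substream(seed, "relatedness")
    removed: list[str] = []
    while graph.number_of_edges() > 0:
        degrees = dict(graph.degree())
        top = max(degrees.values())
        candidates = sorted(n for n, d in degrees.items() if d == top)
        victim = candidates[rng.integers(len(candidates))]
        graph.remove_node(victim)
        removed.append(victim)
    log.append(f"removed {len(removed)} related sample(s)")
    keep = ~table["sample_id"].astype(str).isin(removed)
    return table.loc[keep].reset_index(drop=True), log
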