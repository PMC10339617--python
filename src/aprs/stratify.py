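"""Percentile stratification of scores and joint score x family-history groups.

Samples are cut into low / intermediate / high groups at the 20th and 80th
empirical percentiles of the adjusted score, either within each population
(the convention for odds-ratio analyses: each population is stratified
against its own distribution) or cohort-wide (the convention for comparing
high-score fractions across populations).  The three score groups crossed
with the binary family-history flag give six joint strata, with
intermediate-score / FH-negative as the reference level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adjust import _empirical_percentile

__all__ = [
    "percentile_groups",
    "joint_fh_groups",
    "GROUP_LEVELS",
    "JOINT_LEVELS",
    "JOINT_REFERENCE",
]

GROUP_LEVELS = ["low", "intermediate", "high"]

JOINT_LEVELS = [
    "intermediate_fh_neg",  # reference level first
    "low_fh_neg",
    "low_fh_pos",
    "intermediate_fh_pos",
    "high_fh_neg",
    "high_fh_pos",
]
JOINT_REFERENCE = "intermediate_fh_neg"


def percentile_groups(
    scores,
    labels=None,
    low_cut: float = 20.0,
    high_cut: float = 80.0,
    reference: str = "within_population",
) -> pd.Series:
    """Low/intermediate/high group per sample.

    ``low`` means the sample's whole tie class lies within the bottom
    ``low_cut`` percent of the reference distribution (strictly below the
    order statistic at ``floor(low_cut*n/100) + 1``); ``high`` means it lies
    within the top ``100 - high_cut`` percent (strictly above the order
    statistic at ``ceil(high_cut*n/100)``).  Ties straddling a cut fall
    inward to ``intermediate``; with ``n`` divisible by 5 and no boundary
    ties the default cuts give exactly 20% low and 20% high.  In
    ``within_population`` mode cuts are computed per population (each
    stratum needs >= 5 samples); in ``cohort_wide`` mode one pair of cuts
    serves everyone.
    """
    if not (0.0 < low_cut < high_cut < 100.0):
        raise ValueError("cuts must satisfy 0 < low_cut < high_cut < 100")
    if reference not in ("within_population", "cohort_wide"):
        raise ValueError(f"unknown reference mode {reference!r}")
    x = np.asarray(scores, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    out = np.full(len(x), "intermediate", dtype=object)

    def cut_and_assign(mask: np.ndarray) -> None:
        xs = np.sort(x[mask])
        n = len(xs)
        lo = xs[min(int(np.floor(low_cut * n / 100.0)), n - 1)]
        hi = _empirical_percentile(x[mask], high_cut)
        out[mask & (x < lo)] = "low"
        out[mask & (x > hi)] = "high"

    if reference == "cohort_wide" or labels is None:
        cut_and_assign(np.ones(len(x), dtype=bool))
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            mask = labels == lab
            if mask.sum() < 5:
                raise ValueError(
                    f"population {lab!r} has {int(mask.sum())} samples; "
                    "need >= 5 for within-population percentiles"
                )
            cut_and_assign(mask)
    return pd.Series(
        pd.Categorical(out, categories=GROUP_LEVELS), name="aprs_group"
    )


def joint_fh_groups(groups, fh) -> pd.Series:
    """Six-level score-group x family-history factor.

    Missing FH drops the sample (NaN in the output, to be filtered by the
    caller with a log entry).  The reference level is fixed to
    intermediate-score / FH-negative.
    """
    g = pd.Series(groups).astype(str).to_numpy()
    f = pd.Series(fh, dtype="float").to_numpy()
    if len(g) != len(f):
        raise ValueError("groups and FH flags differ in length")
    out = np.full(len(g), None, dtype=object)
    ok = ~np.isnan(f)
    suffix = np.where(f == 1, "fh_pos", "fh_neg")
    out[ok] = np.char.add(np.char.add(g[ok].astype(str), "_"), suffix[ok])
    return pd.Series(
        pd.Categorical(out, categories=JOINT_LEVELS), name="joint_group"
    )
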