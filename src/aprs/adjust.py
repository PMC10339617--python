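"""Ancestry adjustment of PRS by principal-component residualization.

A pooled ordinary-least-squares model ``PRS ~ 1 + PC1 + PC2 + PC3 + PC4`` is
fitted across all samples; the adjusted score (aPRS) is the residual,
re-standardized to mean 0 / SD 1.  Residualization removes the component of
the score explained by genome-wide ancestry, so score percentiles become
comparable across populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import standardize

__all__ = ["AdjustmentResult", "adjust_prs", "high_prs_fraction"]


@dataclass
class AdjustmentResult:
    """aPRS vector plus the regression it came from."""

    aprs: np.ndarray
    coefficients: pd.Series
    dropped_columns: list[str]
    r_squared: float


def adjust_prs(prs, pcs: pd.DataFrame) -> AdjustmentResult:
    """Residualize a (standardized) PRS on PCs and re-standardize.

    ``pcs`` holds one column per component (any number; the pipeline default
    is four).  Constant PC columns carry no ancestry information and are
    dropped with a warning so degenerate toy inputs still run; genuinely
    collinear non-constant columns raise.  Raises if the residual variance is
    zero (the score is an exact linear function of the PCs).
    """
    y = np.asarray(prs, dtype=float)
    n = len(y)
    if n <= 5:
        raise ValueError("need more than 5 samples to adjust")
    if len(pcs) != n:
        raise ValueError("PRS and PC table lengths differ")
    cols = list(pcs.columns)
    x_full = pcs.to_numpy(dtype=float)
    keep, dropped = [], []
    for j, c in enumerate(cols):
        if np.ptp(x_full[:, j]) == 0.0:
            dropped.append(c)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(
            f"constant PC column(s) dropped from adjustment: {dropped}",
            stacklevel=2,
        )
    x = np.column_stack([np.ones(n)] + [x_full[:, j] for j in keep])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"PC design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"columns: {['intercept'] + [cols[j] for j in keep]}"
        )
    # QR least squares (via lstsq, which is SVD-based and equally stable)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    if resid.std() <= 1e-10 * max(1.0, np.abs(y).max()):
        raise ValueError(
            "zero residual variance: PRS is an exact linear function of the PCs"
        )
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / tss if tss > 0 else 0.0
    names = ["intercept"] + [cols[j] for j in keep]
    return AdjustmentResult(
        aprs=standardize(resid),
        coefficients=pd.Series(beta, index=names, name="coefficient"),
        dropped_columns=dropped,
        r_squared=r2,
    )


def high_prs_fraction(
    scores, labels, threshold_percentile: float = 80.0
) -> pd.Series:
    """Per-population fraction above the cohort-wide percentile threshold.

    The threshold is the empirical ``threshold_percentile``-th percentile of
    the whole cohort (order statistic at ``ceil(q*n/100)``); "high" means
    strictly above it.  With an ancestry-shifted raw score the fractions
    diverge sharply between populations; after PC adjustment each population
    should sit near ``1 - q/100``.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 populations")
    cut = _empirical_percentile(x, threshold_percentile)
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        out[str(lab)] = float((x[mask] > cut).mean())
    return pd.Series(out, name="high_fraction")


def _empirical_percentile(x: np.ndarray, q: float) -> float:
    """Order statistic at ceil(q*n/100) — the pinned quantile convention."""
    n = len(x)
    rank = int(np.ceil(q * n / 100.0))
    rank = min(max(rank, 1), n)
    return float(np.sort(x)[rank - 1])
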