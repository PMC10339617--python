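"""Cox proportional-hazards modelling on the age scale.

Age at diagnosis is the event time for cases; age at the most recent visit is
the censoring time for controls.  The partial likelihood uses Efron tie
handling (ages are coarse, ties are certain).  The proportional-hazards
assumption is checked with the Grambsch–Therneau scaled-Schoenfeld test
(identity time transform, pinned for determinism), per covariate and
globally.  Covariate-adjusted cumulative incidence curves ``1 - S(t)`` are
produced per stratum with the remaining covariates held at cohort means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "CoxFit",
    "fit_cox",
    "test_proportional_hazards",
    "adjusted_cumulative_incidence",
]


@dataclass
class CoxFit:
    """A fitted Cox model plus the data needed for diagnostics and curves."""

    summary: pd.DataFrame = field(repr=False)
    duration_col: str = "time"
    event_col: str = "event"
    covariates: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0
    _fitter: CoxPHFitter = field(default=None, repr=False)
    _data: pd.DataFrame = field(default=None, repr=False)

    def hazard_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.summary.set_index("term").loc[term]
        return float(row["hr"]), float(row["ci_low"]), float(row["ci_high"])


def fit_cox(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
) -> CoxFit:
    """Fit a Cox model by Efron partial likelihood.

    Constant covariates are dropped with a warning (they cannot be
    estimated); zero or negative durations, fewer than two events, and
    monotone-likelihood divergence raise.
    """
    if covariate_cols is None:
        covariate_cols = [
            c for c in data.columns if c not in (duration_col, event_col)
        ]
    t = data[duration_col].to_numpy(dtype=float)
    e = data[event_col].to_numpy(dtype=float)
    if (t <= 0).any():
        raise ValueError("durations must be strictly positive")
    n_events = int(e.sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    keep = []
    for c in covariate_cols:
        if np.ptp(data[c].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"constant covariate {c!r} excluded", stacklevel=2)
        else:
            keep.append(c)
    if not keep:
        raise ValueError("no non-constant covariates to fit")
    df = data[[duration_col, event_col] + keep].astype(float).reset_index(drop=True)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as err:
        raise ValueError(f"Cox fit failed: {err}") from err
    params = cph.params_
    se = cph.standard_errors_
    diverged = (params.abs() > 30) | (se > 100 * params.abs().clip(lower=1.0))
    if diverged.any():
        worst = list(params.index[diverged])
        raise ValueError(
            f"monotone likelihood: coefficient(s) for {worst} diverge "
            "(infinite maximum of the partial likelihood)"
        )
    s = cph.summary
    summary = pd.DataFrame(
        {
            "term": s.index,
            "estimate": s["coef"].to_numpy(),
            "se": s["se(coef)"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": s["exp(coef) lower 95%"].to_numpy(),
            "ci_high": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CoxFit(
        summary=summary,
        duration_col=duration_col,
        event_col=event_col,
        covariates=keep,
        n=len(df),
        n_events=n_events,
        _fitter=cph,
        _data=df,
    )


def test_proportional_hazards(fit: CoxFit) -> pd.DataFrame:
    """Grambsch–Therneau proportional-hazards test (identity time transform).

    For event times :math:`t_k` with Schoenfeld residuals :math:`s_k`, the
    statistic uses the centered transform :math:`\\tilde g_k = t_k - \\bar t`:
    per covariate ``chi2_j = d (Vu)_j^2 / (V_jj * sum g~^2)`` and globally
    ``chi2 = d u' V u / sum g~^2`` with ``u = sum g~_k s_k``, ``V`` the
    coefficient covariance and ``d`` the event count.  Returns one row per
    covariate plus a ``GLOBAL`` row with (chi2, df, p).
    """
    if fit.n_events < 3:
        raise ValueError("need >= 3 events to test proportional hazards")
    cph: CoxPHFitter = fit._fitter
    resid = cph.compute_residuals(fit._data, kind="schoenfeld")
    # residual rows correspond to event observations, in event-time order
    g = fit._data.loc[resid.index, fit.duration_col].to_numpy(dtype=float)
    g = g - g.mean()
    ssq = float((g**2).sum())
    s = resid[fit.covariates].to_numpy(dtype=float)
    u = s.T @ g
    v = cph.variance_matrix_.loc[fit.covariates, fit.covariates].to_numpy()
    d = fit.n_events
    vu = v @ u
    rows = []
    for j, c in enumerate(fit.covariates):
        chi2 = d * vu[j] ** 2 / (v[j, j] * ssq)
        rows.append((c, chi2, 1, float(stats.chi2.sf(chi2, 1))))
    chi2_g = float(d * (u @ vu) / ssq)
    p_g = float(stats.chi2.sf(chi2_g, len(fit.covariates)))
    rows.append(("GLOBAL", chi2_g, len(fit.covariates), p_g))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])


def adjusted_cumulative_incidence(
    fit: CoxFit,
    strata: dict[str, dict[str, float]],
    ages: np.ndarray,
) -> pd.DataFrame:
    """Adjusted cumulative incidence ``1 - S(t)`` per stratum.

    Each stratum is a mapping of covariate overrides (typically its dummy
    indicators); every remaining covariate sits at its cohort mean — the
    conditional-at-means convention.  Strata referencing unknown covariates
    are omitted with a warning.  Returns a frame indexed by age with one
    column per stratum; curves are non-decreasing and start at 0 for ages
    before the first event.
    """
    ages = np.asarray(ages, dtype=float)
    means = fit._data[fit.covariates].mean()
    profiles, labels = [], []
    for label, overrides in strata.items():
        unknown = set(overrides) - set(fit.covariates)
        if unknown:
            warnings.warn(
                f"stratum {label!r} references unknown covariate(s) "
                f"{sorted(unknown)}; omitted",
                stacklevel=2,
            )
            continue
        row = means.copy()
        for k, val in overrides.items():
            row[k] = val
        profiles.append(row)
        labels.append(label)
    if not profiles:
        raise ValueError("no valid stratum profiles")
    x = pd.DataFrame(profiles).reset_index(drop=True)
    surv = fit._fitter.predict_survival_function(x, times=ages)
    out = 1.0 - surv
    # no event can have occurred before the first observed event time
    first_event = fit._data.loc[
        fit._data[fit.event_col] == 1, fit.duration_col
    ].min()
    out.loc[out.index < first_event] = 0.0
    out.columns = labels
    out.index.name = "age"
    return out
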