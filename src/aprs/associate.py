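"""Logistic association models, odds ratios, and discrimination metrics.

Three model shapes are provided, mirroring a score-portability analysis:

1. continuous — ``logit P(Y=1) = b0 + b_aprs*aPRS + b_sex*sex + b_age*age +
   sum_k b_pck*PCk``;
2. three score groups (low / intermediate / high), intermediate as reference;
3. six joint score x family-history groups, intermediate/FH-negative as
   reference.

ORs are ``exp(beta)`` with Wald 95% CIs; p-values below 0.01 are flagged.
Discrimination is evaluated on a held-out test split: AUROC as the midrank
Mann–Whitney statistic with a DeLong (paired-rank asymptotic) CI, AUPRC as
the step-interpolated precision-recall integral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import average_precision_score
from sklearn.model_selection import train_test_split

from ._rng import substream
from .stratify import GROUP_LEVELS, JOINT_LEVELS, JOINT_REFERENCE

__all__ = [
    "ModelFit",
    "EvaluationResult",
    "fit_logistic",
    "fit_group_model",
    "fit_fh_joint_model",
    "interaction_lr_test",
    "crude_or_2x2",
    "split_train_test",
    "evaluate_discrimination",
    "downsample_to_ratio",
    "SIGNIFICANCE_LEVEL",
]

#: two-sided level below which a p-value is star-flagged
SIGNIFICANCE_LEVEL = 0.01

_Z95 = stats.norm.ppf(0.975)


@dataclass
class ModelFit:
    """A fitted logistic model: per-term estimates, ORs with 95% CIs."""

    terms: pd.DataFrame = field(repr=False)
    log_likelihood: float = np.nan
    n: int = 0
    converged: bool = False
    _result: object = field(default=None, repr=False)

    def odds_ratio(self, term: str) -> tuple[float, float, float]:
        """(OR, CI low, CI high) for one term."""
        row = self.terms.set_index("term").loc[term]
        return float(row["or"]), float(row["ci_low"]), float(row["ci_high"])

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(design.astype(float), has_constant="add")
        return np.asarray(self._result.predict(x[self._result.model.exog_names]))


def _check_separation(y: np.ndarray, design: pd.DataFrame) -> list[str]:
    culprits = []
    for col in design.columns:
        x = design[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        if len(x0) and len(x1) and (x0.max() < x1.min() or x1.max() < x0.min()):
            culprits.append(col)
    return culprits


def fit_logistic(outcome, design: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood logistic fit with Wald standard errors.

    ``design`` holds the named covariate columns (no intercept; one is
    added).  Complete separation and non-convergence raise informative
    errors rather than returning unusable estimates.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if design.shape[0] != len(y):
        raise ValueError("outcome and design lengths differ")
    if design.shape[0] <= design.shape[1] + 1:
        raise ValueError("need more observations than model columns")
    x = sm.add_constant(design.astype(float), has_constant="add")
    model = sm.Logit(y, x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", tol=1e-8, maxiter=200, disp=0)
    except Exception as err:  # statsmodels PerfectSeparationError et al.
        culprits = _check_separation(y, design)
        if culprits:
            raise ValueError(
                f"complete separation on column(s): {culprits}"
            ) from err
        raise
    if not res.mle_retvals.get("converged", False):
        raise ValueError(
            "logistic fit did not converge within "
            f"{res.mle_retvals.get('iterations', '?')} iterations"
        )
    if np.abs(res.params.to_numpy()).max() > 50:
        culprits = _check_separation(y, design)
        raise ValueError(
            "diverging coefficient (quasi-separation)"
            + (f" on column(s): {culprits}" if culprits else "")
        )
    beta = res.params
    se = res.bse
    terms = pd.DataFrame(
        {
            "term": beta.index,
            "estimate": beta.to_numpy(),
            "se": se.to_numpy(),
            "or": np.exp(beta.to_numpy()),
            "ci_low": np.exp(beta.to_numpy() - _Z95 * se.to_numpy()),
            "ci_high": np.exp(beta.to_numpy() + _Z95 * se.to_numpy()),
            "p": res.pvalues.to_numpy(),
        }
    )
    terms["significant"] = terms["p"] < SIGNIFICANCE_LEVEL
    return ModelFit(
        terms=terms,
        log_likelihood=float(res.llf),
        n=len(y),
        converged=True,
        _result=res,
    )


def _group_dummies(
    groups, levels: list[str], reference: str, allow_empty: bool
) -> pd.DataFrame:
    g = pd.Series(groups).astype(str)
    unknown = set(g.unique()) - set(levels)
    if unknown:
        raise ValueError(f"unknown group level(s): {sorted(unknown)}")
    cols = {}
    for level in levels:
        if level == reference:
            continue
        ind = (g == level).astype(float)
        if ind.sum() == 0:
            if not allow_empty:
                raise ValueError(f"group level {level!r} is empty")
            warnings.warn(
                f"empty group level {level!r} dropped from the design",
                stacklevel=3,
            )
            continue
        cols[level] = ind.to_numpy()
    return pd.DataFrame(cols)


def fit_group_model(
    outcome, groups, covariates: pd.DataFrame | None = None
) -> ModelFit:
    """Logistic model on the three score groups, intermediate as reference."""
    design = _group_dummies(groups, GROUP_LEVELS, "intermediate", allow_empty=False)
    if covariates is not None:
        design = pd.concat(
            [design.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1
        )
    return fit_logistic(outcome, design)


def fit_fh_joint_model(
    outcome, joint_groups, covariates: pd.DataFrame | None = None
) -> ModelFit:
    """Logistic model on the six score x FH groups (five dummies).

    An empty joint cell drops its dummy with a warning rather than erroring,
    since sparse cells are expected in small strata.
    """
    design = _group_dummies(
        joint_groups, JOINT_LEVELS, JOINT_REFERENCE, allow_empty=True
    )
    if covariates is not None:
        design = pd.concat(
            [design.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1
        )
    return fit_logistic(outcome, design)


def interaction_lr_test(
    outcome, groups, fh, covariates: pd.DataFrame | None = None
) -> tuple[float, float, int]:
    """Likelihood-ratio test of score-group x FH interaction.

    Compares the additive model (group dummies + FH) against the model with
    the product terms added.  Returns (chi2, p, df).
    """
    base = _group_dummies(groups, GROUP_LEVELS, "intermediate", allow_empty=False)
    f = pd.Series(fh, dtype=float).to_numpy()
    base["fh"] = f
    inter = base.copy()
    df_added = 0
    for level in ("low", "high"):
        col = base[level].to_numpy() * f
        if col.sum() > 0:
            inter[f"{level}_x_fh"] = col
            df_added += 1
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        base = pd.concat([base.reset_index(drop=True), cov], axis=1)
        inter = pd.concat([inter.reset_index(drop=True), cov], axis=1)
    fit0 = fit_logistic(outcome, base)
    fit1 = fit_logistic(outcome, inter)
    chi2 = 2.0 * (fit1.log_likelihood - fit0.log_likelihood)
    p = float(stats.chi2.sf(chi2, df_added))
    return float(chi2), p, df_added


def crude_or_2x2(
    a: float, b: float, c: float, d: float
) -> tuple[float, tuple[float, float], bool]:
    """Crude odds ratio ``ad/bc`` from a 2x2 table, with Wald 95% CI.

    Layout: ``a`` exposed cases, ``b`` exposed controls, ``c`` unexposed
    cases, ``d`` unexposed controls.  A zero cell triggers the
    Haldane–Anscombe 0.5 correction (flag returned True); two zero cells in
    one margin leave the OR undefined and raise.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    zero = counts == 0
    if (zero[0] and zero[1]) or (zero[2] and zero[3]) or (zero[0] and zero[2]) or (
        zero[1] and zero[3]
    ):
        raise ValueError("two empty cells share a margin; OR undefined")
    corrected = bool(zero.any())
    if corrected:
        counts = counts + 0.5
    a_, b_, c_, d_ = counts
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1.0 / counts).sum())
    lo, hi = np.exp(np.log(or_) - _Z95 * se), np.exp(np.log(or_) + _Z95 * se)
    return float(or_), (float(lo), float(hi)), corrected


def split_train_test(
    table: pd.DataFrame,
    outcome_col: str,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Outcome-stratified train/test index split (default 75/25).

    Returns positional index arrays.  Stratification keeps cases in both
    sets; an input without both classes raises.
    """
    if len(table) < 8:
        raise ValueError("need at least 8 samples to split")
    y = table[outcome_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("cannot split: outcome has a single class")
    rng = substream(seed, "train_test_split")
    idx = np.arange(len(table))
    train, test = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    if y[train].sum() == 0 or y[test].sum() == 0:
        raise ValueError(
            "a split set has zero cases; change the stratification seed"
        )
    return np.sort(train), np.sort(test)


@dataclass
class EvaluationResult:
    """Held-out discrimination of one model."""

    label: str
    auroc: float
    auroc_ci: tuple[float, float]
    auprc: float
    n_test: int
    n_cases_test: int


def _auroc_delong(y: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Midrank AUROC and its DeLong variance."""
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = all_ranks[:n1]
    auc = (r_pos.sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # placement values (structural components)
    v10 = (r_pos - stats.rankdata(pos)) / n0
    r_neg = all_ranks[n1:]
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / n1
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    return float(auc), float(var)


def evaluate_discrimination(
    y_test, predictions, label: str = "model"
) -> EvaluationResult:
    """AUROC (with DeLong 95% CI) and AUPRC on test predictions."""
    y = np.asarray(y_test, dtype=int)
    s = np.asarray(predictions, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    auc, var = _auroc_delong(y, s)
    half = _Z95 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    auprc = float(average_precision_score(y, s))
    return EvaluationResult(
        label=label,
        auroc=auc,
        auroc_ci=ci,
        auprc=auprc,
        n_test=len(y),
        n_cases_test=int(y.sum()),
    )


def downsample_to_ratio(
    table: pd.DataFrame,
    outcome_col: str,
    target_ratio: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly drop cases (or controls) to reach a target case:control ratio.

    ``target_ratio`` is cases per control.  The over-represented side is
    thinned (seeded) until the realized ratio matches the target within one
    sample.  An unachievable target (both sides would need to grow) raises.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    y = table[outcome_col].to_numpy()
    n_case, n_ctrl = int(y.sum()), int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("need both cases and controls to downsample")
    rng = substream(seed, "downsample")
    current = n_case / n_ctrl
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if current > target_ratio:
        keep_cases = int(round(target_ratio * n_ctrl))
        if keep_cases < 1:
            raise ValueError("target ratio leaves no cases; raise the target")
        case_idx = np.sort(rng.choice(case_idx, size=keep_cases, replace=False))
    elif current < target_ratio:
        keep_ctrl = int(round(n_case / target_ratio))
        if keep_ctrl < 1:
            raise ValueError("target ratio leaves no controls; lower the target")
        ctrl_idx = np.sort(rng.choice(ctrl_idx, size=keep_ctrl, replace=False))
    keep = np.sort(np.concatenate([case_idx, ctrl_idx]))
    return table.iloc[keep].reset_index(drop=True)
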