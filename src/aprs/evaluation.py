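"""Simulation studies validating the pipeline end to end.

Each function sets up a named study at a fixed design (sample sizes, effect
sizes, replicate counts chosen to make the Monte-Carlo error small relative
to the property being checked), runs the relevant pipeline stages from
scratch, and returns the measured quantities.  The studies double as the
package's acceptance benchmarks: the test suite asserts on their outputs and
``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .adjust import adjust_prs, high_prs_fraction
from .ancestry import fit_reference_pca
from .associate import (
    evaluate_discrimination,
    fit_group_model,
    fit_logistic,
    split_train_test,
)
from .scoring import compute_prs, harmonize, standardize
from .simulate import (
    AGE_CENTER,
    AGE_SCALE,
    PopulationSpec,
    SimulationConfig,
    simulate_phenotype,
    simulate_study_cohort,
)
from .stratify import percentile_groups
from .survival import fit_cox, test_proportional_hazards

__all__ = [
    "score_cohort",
    "distribution_shift_study",
    "logistic_coverage_study",
    "null_group_or_study",
    "discrimination_gain_study",
    "cox_recovery_study",
    "schoenfeld_calibration_study",
]

_Z95 = 1.959963984540054


def score_cohort(cohort) -> np.ndarray:
    """Standardized PRS of a simulated cohort via the scoring pipeline."""
    harm = harmonize(cohort.scoring, cohort.genotypes)
    return standardize(compute_prs(harm, cohort.genotypes).to_numpy())


def distribution_shift_study(
    seed: int = 1,
    n_per_population: int = 5000,
    n_variants: int = 1000,
    fst: float = 0.1,
    weight_freq_coupling: float = 0.1,
) -> dict:
    """Structure-driven score shift and its removal by PC residualization.

    Two populations with differentiated allele frequencies and scoring
    weights coupled to the frequency differences: the raw standardized PRS
    then lands very different fractions of each population above the
    cohort-wide 80th percentile.  After residualizing on the first four
    within-cohort PCs, each population should sit near 20%.

    Returns raw and adjusted high-score fractions per population, and the
    aPRS/PC diagnostics (max |correlation| with PC1-4, mean, SD).
    """
    specs = [
        PopulationSpec("EUR", n_per_population, fst=fst),
        PopulationSpec("SAS", n_per_population, fst=fst),
    ]
    config = SimulationConfig(
        n_variants=n_variants, seed=seed, weight_freq_coupling=weight_freq_coupling
    )
    cohort = simulate_study_cohort(specs, config)
    prs = score_cohort(cohort)
    model = fit_reference_pca(cohort.genotypes, k=4)
    pcs = model.reference_scores[["pc1", "pc2", "pc3", "pc4"]]
    result = adjust_prs(prs, pcs)
    labels = cohort.genotypes.populations
    raw = high_prs_fraction(prs, labels)
    adj = high_prs_fraction(result.aprs, labels)
    max_corr = max(
        abs(float(np.corrcoef(result.aprs, pcs[c])[0, 1])) for c in pcs.columns
    )
    return {
        "raw_fraction": raw.to_dict(),
        "adjusted_fraction": adj.to_dict(),
        "aprs_pc_max_abs_corr": max_corr,
        "aprs_mean": float(result.aprs.mean()),
        "aprs_sd": float(result.aprs.std()),
        "n": 2 * n_per_population,
    }


def logistic_coverage_study(
    seed: int = 1, n_replicates: int = 200, n: int = 5000, beta_aprs: float = 0.5
) -> dict:
    """Wald 95% CI coverage for a known continuous score effect.

    Outcomes are drawn from the logistic model the estimator assumes
    (score, sex, age and four noise PCs as covariates), so nominal coverage
    is the truth being recovered.
    """
    rng = substream(seed, "logistic_coverage")
    covered = 0
    for _ in range(n_replicates):
        design = pd.DataFrame(
            {
                "aprs": rng.normal(size=n),
                "sex": rng.integers(0, 2, n).astype(float),
                "age": rng.normal(size=n),
                **{f"pc{k}": rng.normal(size=n) for k in range(1, 5)},
            }
        )
        lp = -2.2 + beta_aprs * design["aprs"] + 0.3 * design["sex"] + 0.2 * design["age"]
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
        fit = fit_logistic(y, design)
        t = fit.terms.set_index("term")
        est, se = t.loc["aprs", "estimate"], t.loc["aprs", "se"]
        if est - _Z95 * se <= beta_aprs <= est + _Z95 * se:
            covered += 1
    return {"coverage": covered / n_replicates, "n": n, "replicates": n_replicates}


def null_group_or_study(
    seed: int = 1,
    n_replicates: int = 200,
    n_per_population: int = 2500,
    n_variants: int = 60,
) -> dict:
    """High-vs-intermediate OR confidence intervals under a null score.

    Full generator-to-model round trip with ``beta_prs = 0``: liability
    cases, scored PRS, within-population percentile groups, covariate-
    adjusted group model.  The high-group CI should cover OR = 1 in at
    least ~95% of replicates (the criterion asks >= 90%).
    """
    rng = substream(seed, "null_group_or")
    covered = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        specs = [
            PopulationSpec("EUR", n_per_population, fst=0.1),
            PopulationSpec("SAS", n_per_population, fst=0.1),
        ]
        config = SimulationConfig(
            n_variants=n_variants, seed=rep_seed, beta_prs=0.0, prevalence=0.1
        )
        cohort = simulate_study_cohort(specs, config)
        cov = simulate_phenotype(cohort, config)
        prs = score_cohort(cohort)
        groups = percentile_groups(prs, cov["population"].to_numpy())
        design = pd.DataFrame(
            {
                "sex": cov["sex"].astype(float),
                "age": (cov["age"] - AGE_CENTER) / AGE_SCALE,
            }
        )
        fit = fit_group_model(cov["case_disease"].to_numpy(), groups, design)
        _, lo, hi = fit.odds_ratio("high")
        if lo <= 1.0 <= hi:
            covered += 1
    return {
        "coverage": covered / n_replicates,
        "n": 2 * n_per_population,
        "replicates": n_replicates,
    }


def discrimination_gain_study(
    seed: int = 1,
    betas: tuple[float, ...] = (0.3, 0.5, 0.7),
    n_eur: int = 4000,
    n_sas: int = 1000,
    n_variants: int = 100,
) -> dict:
    """Held-out AUROC gain from adding the score to a covariate model.

    For each generative score effect on the grid: simulate a cohort, split
    75/25 stratified by outcome, fit covariates-only and covariates+score
    on the training set, and compare test AUROC.  A positive generative
    effect must yield a positive gain at every grid point.
    """
    rng = substream(seed, "discrimination")
    gains = {}
    for beta in betas:
        rep_seed = int(rng.integers(2**31))
        specs = [
            PopulationSpec("EUR", n_eur, fst=0.1),
            PopulationSpec("SAS", n_sas, fst=0.1),
        ]
        config = SimulationConfig(
            n_variants=n_variants, seed=rep_seed, beta_prs=beta, prevalence=0.1
        )
        cohort = simulate_study_cohort(specs, config)
        cov = simulate_phenotype(cohort, config)
        table = cov.copy()
        table["aprs"] = score_cohort(cohort)
        table["age_std"] = (table["age"] - AGE_CENTER) / AGE_SCALE
        y = table["case_disease"].to_numpy()
        train, test = split_train_test(table, "case_disease", seed=rep_seed)
        base = table[["sex", "age_std"]].astype(float)
        full = table[["sex", "age_std", "aprs"]].astype(float)
        fit0 = fit_logistic(y[train], base.iloc[train])
        fit1 = fit_logistic(y[train], full.iloc[train])
        auc0 = evaluate_discrimination(y[test], fit0.predict(base.iloc[test])).auroc
        auc1 = evaluate_discrimination(y[test], fit1.predict(full.iloc[test])).auroc
        gains[beta] = auc1 - auc0
    return {"auroc_gain": gains, "n": n_eur + n_sas}


def cox_recovery_study(seed: int = 1, n: int = 10_000, hr: float = 2.0) -> dict:
    """Two-group exponential onset simulation: the fitted HR should recover
    the generative hazard ratio."""
    rng = substream(seed, "cox_recovery")
    grp = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.01 * hr**grp))
    c = rng.uniform(40, 200, n)
    event = (t <= c).astype(int)
    df = pd.DataFrame(
        {
            "time": np.maximum(np.where(event == 1, t, c), 1e-6),
            "event": event,
            "grp": grp.astype(float),
        }
    )
    fit = fit_cox(df, covariate_cols=["grp"])
    est, lo, hi = fit.hazard_ratio("grp")
    return {"hr": est, "ci": (lo, hi), "true_hr": hr, "n": n}


def schoenfeld_calibration_study(
    seed: int = 1, n_replicates: int = 500, n: int = 1500, alpha: float = 0.05
) -> dict:
    """Type-I error of the global proportional-hazards test.

    Replicates are drawn from a PH-respecting exponential model (two
    covariates); the global Grambsch–Therneau test should reject at close
    to the nominal level.  The replicate size is chosen large enough for
    the asymptotic chi-square reference to be accurate.
    """
    rng = substream(seed, "schoenfeld_calibration")
    rejections = 0
    for _ in range(n_replicates):
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.4 * x1 + 0.3 * x2)))
        c = rng.uniform(10, 80, n)
        event = (t <= c).astype(int)
        df = pd.DataFrame(
            {
                "time": np.where(event == 1, t, c),
                "event": event,
                "x1": x1,
                "x2": x2,
            }
        )
        fit = fit_cox(df, covariate_cols=["x1", "x2"])
        ph = test_proportional_hazards(fit).set_index("term")
        if ph.loc["GLOBAL", "p"] < alpha:
            rejections += 1
    return {
        "type_i_error": rejections / n_replicates,
        "n": n,
        "replicates": n_replicates,
        "alpha": alpha,
    }
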