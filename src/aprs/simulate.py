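"""Synthetic two-population cohorts with the structure the pipeline assumes.

The generator emulates, at desk scale, a biobank-style study of a polygenic
disease in two ancestry groups:

* **Population structure** follows the Balding–Nichols F-model: each variant
  has an ancestral allele frequency :math:`p_0`, and every population draws
  its own frequency from :math:`\\mathrm{Beta}(p_0(1-F)/F,\\,(1-p_0)(1-F)/F)`,
  whose mean is :math:`p_0` and variance :math:`F\\,p_0(1-p_0)`.  Genotypes
  are Hardy–Weinberg binomial draws within population; variants are unlinked.
* **Disease** follows a liability-threshold model: a standard-normal latent
  liability loads on the standardized true polygenic score, sex, and age, and
  a case is anyone above the quantile matching the target prevalence.
* **Family history** is generated mechanistically: each proband gets
  first-degree relatives whose genetic scores correlate 0.5 with the
  proband's, who share a family environment term, and who are affected by the
  same liability threshold; FH = 1 iff any relative is affected.
* **Onset ages** come from a proportional-hazards model on the age scale with
  a constant baseline hazard; a sample whose onset falls after its
  recruitment visit is a censored control.

All randomness derives from one master seed through named substreams, so
re-running or adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .containers import GenotypeSet, ScoringFile

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_reference_panel",
    "simulate_study_cohort",
    "simulate_scoring_file",
    "simulate_phenotype",
    "simulate_family_history",
    "simulate_onset_ages",
    "simulate_cohort",
]

# Recruitment-age model: uniform on [40, 69]; liability uses age standardized
# by the approximate biobank mean/SD so beta_age is per-SD.
AGE_MIN, AGE_MAX = 40.0, 69.0
AGE_CENTER, AGE_SCALE = 54.5, 8.4
_VAR_AGE_STD = ((AGE_MAX - AGE_MIN) ** 2 / 12.0) / AGE_SCALE**2
_VAR_SEX = 0.25  # Bernoulli(0.5), centered coding

_NONAMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: a label, a size and its differentiation F."""

    label: str
    n_samples: int
    fst: float = 0.1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; one master seed drives every stage.

    ``prevalence`` may be a single float (one cohort-wide threshold) or a
    mapping from population label to prevalence.
    """

    n_variants: int = 1000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    weight_mean: float = 0.0
    weight_sd: float = 0.1
    #: linear coupling of a variant's weight to its between-population
    #: effect-allele frequency difference; nonzero values shift the raw PRS
    #: distribution between populations (the portability failure mode the
    #: PC adjustment is meant to remove)
    weight_freq_coupling: float = 0.0
    ambiguous_fraction: float = 0.1
    flipped_fraction: float = 0.1
    prevalence: float | dict[str, float] = 0.1
    beta_prs: float = 0.5
    beta_sex: float = 0.3
    beta_age: float = 0.3
    fh_shared_env: float = 0.05
    n_relatives: int = 3
    hazard_baseline: float = 0.002
    hazard_beta_prs: float = 0.5
    disease: str = "disease"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 <= self.ambiguous_fraction <= 1.0):
            raise ValueError("ambiguous_fraction must lie in [0, 1]")
        if not (0.0 <= self.flipped_fraction <= 1.0):
            raise ValueError("flipped_fraction must lie in [0, 1]")
        for p in self._prevalences():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence must lie in (0, 1), got {p}")
        if self.fh_shared_env < 0:
            raise ValueError("fh_shared_env must be >= 0")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be >= 0")

    def _prevalences(self) -> list[float]:
        if isinstance(self.prevalence, dict):
            return list(self.prevalence.values())
        return [self.prevalence]

    def prevalence_for(self, label: str) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence[label]
        return self.prevalence

    def residual_variance(self) -> float:
        """Variance left for the liability noise term once fixed effects are in."""
        v = (
            1.0
            - self.beta_prs**2
            - self.beta_sex**2 * _VAR_SEX
            - self.beta_age**2 * _VAR_AGE_STD
        )
        if v <= 0:
            raise ValueError(
                "beta_prs/beta_sex/beta_age leave non-positive liability "
                f"residual variance ({v:.4f}); shrink the effects"
            )
        return v

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "ancestral_freq_range" in d:
            d["ancestral_freq_range"] = tuple(d["ancestral_freq_range"])
        return cls(**d)


@dataclass
class SimulatedCohort:
    """A study cohort plus the ground truth the analysis never sees.

    ``truth`` (per-sample true standardized score, liability components) is
    carried separately from the analysis-visible tables; downstream modules
    must not read it outside of tests.
    """

    genotypes: GenotypeSet
    scoring: ScoringFile
    covariates: pd.DataFrame
    truth: pd.DataFrame = field(repr=False)
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# allele frequencies and genotypes

def _population_frequencies(
    specs: list[PopulationSpec], config: SimulationConfig
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Ancestral and per-population allele frequencies, shared by reference
    panel and study cohort (same seed => same frequencies)."""
    rng = substream(config.seed, "frequencies")
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_variants)
    freqs: dict[str, np.ndarray] = {}
    for spec in specs:
        f = spec.fst
        if f == 0.0:
            freqs[spec.label] = p0.copy()
        else:
            a = p0 * (1.0 - f) / f
            b = (1.0 - p0) * (1.0 - f) / f
            freqs[spec.label] = rng.beta(a, b)
    return p0, freqs


def _variant_metadata(
    specs: list[PopulationSpec], config: SimulationConfig
) -> pd.DataFrame:
    """Variant table with alleles and truth frequency columns.

    A seeded fraction of variants gets strand-ambiguous (A/T or C/G) allele
    pairs; the count is deterministic: round(ambiguous_fraction * n_variants).
    """
    rng = substream(config.seed, "variants")
    m = config.n_variants
    n_amb = int(round(config.ambiguous_fraction * m))
    order = rng.permutation(m)
    is_amb = np.zeros(m, dtype=bool)
    is_amb[order[:n_amb]] = True
    refs = np.empty(m, dtype=object)
    alts = np.empty(m, dtype=object)
    for j in range(m):
        pool = _AMBIGUOUS_PAIRS if is_amb[j] else _NONAMBIGUOUS_PAIRS
        ref, alt = pool[rng.integers(len(pool))]
        refs[j], alts[j] = ref, alt
    p0, freqs = _population_frequencies(specs, config)
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{j + 1}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 1000,
            "ref": refs,
            "alt": alts,
            "ambiguous": is_amb,
            "p_ancestral": p0,
        }
    )
    for label, p in freqs.items():
        df[f"freq_{label}"] = p
    return df


def _draw_genotypes(
    specs: list[PopulationSpec],
    variants: pd.DataFrame,
    rng: np.random.Generator,
    id_prefix: str,
) -> GenotypeSet:
    blocks, labels, samples = [], [], []
    offset = 0
    for spec in specs:
        p = variants[f"freq_{spec.label}"].to_numpy()
        blocks.append(
            rng.binomial(2, p[None, :], size=(spec.n_samples, len(p))).astype(float)
        )
        labels.extend([spec.label] * spec.n_samples)
        samples.extend(
            f"{id_prefix}{i + 1}" for i in range(offset, offset + spec.n_samples)
        )
        offset += spec.n_samples
    return GenotypeSet(
        samples=samples,
        variants=variants,
        dosages=np.vstack(blocks),
        populations=np.array(labels),
    )


def simulate_reference_panel(
    specs: list[PopulationSpec], config: SimulationConfig
) -> GenotypeSet:
    """Reference panel (the stand-in for an external ancestry reference).

    Frequencies are shared with :func:`simulate_study_cohort` under the same
    config, so reference and study samples come from the same populations but
    are independent draws.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 populations for a reference panel")
    variants = _variant_metadata(specs, config)
    rng = substream(config.seed, "reference_genotypes")
    return _draw_genotypes(specs, variants, rng, id_prefix="REF")


def simulate_study_cohort(
    specs: list[PopulationSpec], config: SimulationConfig
) -> SimulatedCohort:
    """Study genotypes plus scoring file and the true score (no phenotypes yet)."""
    variants = _variant_metadata(specs, config)
    rng = substream(config.seed, "study_genotypes")
    genotypes = _draw_genotypes(specs, variants, rng, id_prefix="S")
    scoring = simulate_scoring_file(config, variants)
    truth = _true_scores(genotypes, scoring, variants)
    covariates = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "population": genotypes.populations,
        }
    )
    return SimulatedCohort(
        genotypes=genotypes,
        scoring=scoring,
        covariates=covariates,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# scoring file

def simulate_scoring_file(
    config: SimulationConfig, variants: pd.DataFrame
) -> ScoringFile:
    """Published-style scoring file over the simulated variants.

    Weights are Normal(weight_mean, weight_sd).  When ``weight_freq_coupling``
    is nonzero and the variant table carries two (or more) population
    frequency columns, each weight gains ``coupling * (Δ effect-allele
    frequency)`` between the first two populations, producing the
    structure-driven score shift the PC adjustment must remove.  A seeded
    ``flipped_fraction`` of records is written with effect/other alleles
    swapped relative to the genotype alt/ref orientation, to exercise
    allele-flip handling downstream.
    """
    m = len(variants)
    if m != config.n_variants:
        raise ValueError(
            f"variant metadata has {m} rows but config.n_variants="
            f"{config.n_variants}"
        )
    rng = substream(config.seed, "weights")
    weights = rng.normal(config.weight_mean, config.weight_sd, size=m)

    n_flip = int(round(config.flipped_fraction * m))
    order = rng.permutation(m)
    flipped = np.zeros(m, dtype=bool)
    flipped[order[:n_flip]] = True

    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()
    effect = np.where(flipped, ref, alt)
    other = np.where(flipped, alt, ref)

    if config.weight_freq_coupling != 0.0:
        freq_cols = [c for c in variants.columns if c.startswith("freq_")]
        if len(freq_cols) < 2:
            raise ValueError(
                "weight_freq_coupling requires >= 2 population frequency columns"
            )
        p1 = variants[freq_cols[0]].to_numpy()
        p2 = variants[freq_cols[1]].to_numpy()
        delta_alt = p2 - p1
        # frequency of the listed effect allele differs by -delta when flipped
        delta_eff = np.where(flipped, -delta_alt, delta_alt)
        weights = weights + config.weight_freq_coupling * delta_eff

    records = pd.DataFrame(
        {
            "variant_id": variants["variant_id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "effect_allele": effect,
            "other_allele": other,
            "effect_weight": weights,
        }
    )
    return ScoringFile(records=records, pgs_id="PGSSIM001")


def _true_scores(
    genotypes: GenotypeSet, scoring: ScoringFile, variants: pd.DataFrame
) -> pd.DataFrame:
    """True standardized polygenic score per sample.

    Computed over the non-ambiguous variants only — ambiguous records are
    unknowable to any strand-unaware scorer, so the estimable score (and
    hence the disease model) is defined on the scorable set.
    """
    keep = ~variants["ambiguous"].to_numpy()
    w = scoring.records["effect_weight"].to_numpy()[keep]
    eff = scoring.records["effect_allele"].to_numpy()[keep]
    alt = variants["alt"].to_numpy()[keep]
    d = genotypes.dosages[:, keep]
    d_eff = np.where(eff == alt, d, 2.0 - d)
    raw = d_eff @ w
    sd = raw.std()
    if sd == 0:
        g = np.zeros_like(raw)
    else:
        g = (raw - raw.mean()) / sd
    return pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "population": genotypes.populations,
            "true_score_raw": raw,
            "true_score": g,
        }
    )


# ---------------------------------------------------------------------------
# phenotype, family history, onset

def _thresholds(cohort: SimulatedCohort, config: SimulationConfig) -> np.ndarray:
    pops = cohort.truth["population"].to_numpy()
    return np.array(
        [stats.norm.ppf(1.0 - config.prevalence_for(p)) for p in pops]
    )


def simulate_phenotype(
    cohort: SimulatedCohort, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Assign sex, age and liability-threshold case status; returns covariates.

    Liability ``L = b_prs*G + b_sex*(sex-1/2) + b_age*age_std + c + e`` with
    ``G`` the standardized true score, ``c`` the family-shared environment
    (variance ``fh_shared_env``) and ``e`` independent noise scaled so
    ``Var(L) = 1``; a sample is a case iff ``L`` exceeds the normal quantile
    of ``1 - prevalence`` for its population.  Covariates are centered inside
    the liability so the threshold maps prevalence exactly.
    """
    config = config or cohort.config
    n = len(cohort.truth)
    var_eps = config.residual_variance()
    if config.fh_shared_env > var_eps:
        raise ValueError(
            f"fh_shared_env={config.fh_shared_env} exceeds the liability "
            f"residual variance {var_eps:.4f}"
        )
    rng = substream(config.seed, "phenotype")
    sex = rng.integers(0, 2, size=n).astype(float)
    age = rng.uniform(AGE_MIN, AGE_MAX, size=n)
    age_std = (age - AGE_CENTER) / AGE_SCALE
    shared = rng.normal(0.0, np.sqrt(config.fh_shared_env), size=n)
    noise = rng.normal(0.0, np.sqrt(var_eps - config.fh_shared_env), size=n)
    g = cohort.truth["true_score"].to_numpy()
    liability = (
        config.beta_prs * g
        + config.beta_sex * (sex - 0.5)
        + config.beta_age * age_std
        + shared
        + noise
    )
    case = (liability > _thresholds(cohort, config)).astype(int)

    cov = cohort.covariates
    cov["sex"] = sex.astype(int)
    cov["age"] = age
    cov["visit_age"] = age
    cov[f"case_{config.disease}"] = case
    for flag in ("qc_sex_discordant", "qc_aneuploidy", "qc_het_missing_outlier"):
        cov[flag] = 0
    cohort.truth["liability"] = liability
    cohort.truth["shared_env"] = shared
    return cov


def simulate_family_history(
    cohort: SimulatedCohort, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """First-degree family-history flags via simulated relatives.

    Each proband gets ``n_relatives`` relatives whose genetic score is
    ``0.5*G + sqrt(0.75)*z`` (correlation 0.5 with the proband), who share
    the proband's family environment term, and whose liability uses the same
    threshold.  FH = 1 iff any relative is affected.
    """
    config = config or cohort.config
    if config.n_relatives < 1:
        raise ValueError("n_relatives must be >= 1")
    if "liability" not in cohort.truth.columns:
        raise ValueError("run simulate_phenotype before simulate_family_history")
    rng = substream(config.seed, "family")
    n = len(cohort.truth)
    g = cohort.truth["true_score"].to_numpy()
    shared = cohort.truth["shared_env"].to_numpy()
    var_eps = 1.0 - config.beta_prs**2 - config.fh_shared_env
    if var_eps <= 0:
        raise ValueError("beta_prs and fh_shared_env leave relatives no noise")
    thresh = _thresholds(cohort, config)
    any_affected = np.zeros(n, dtype=bool)
    for _ in range(config.n_relatives):
        g_rel = 0.5 * g + np.sqrt(0.75) * rng.normal(size=n)
        l_rel = (
            config.beta_prs * g_rel
            + shared
            + rng.normal(0.0, np.sqrt(var_eps), size=n)
        )
        any_affected |= l_rel > thresh
    cohort.covariates[f"fh_{config.disease}"] = any_affected.astype(int)
    return cohort.covariates


def simulate_onset_ages(
    cohort: SimulatedCohort, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Draw onset ages from a constant-baseline proportional-hazards model.

    Onset age ``T`` is exponential with rate ``hazard_baseline *
    exp(hazard_beta_prs * G)``.  A sample whose onset falls at or before its
    recruitment visit is an observed case (event time = onset age); one whose
    onset falls after the visit is a censored control (censoring time = visit
    age).  The case column is re-derived from this comparison so event
    indicator and case status agree.
    """
    config = config or cohort.config
    if config.hazard_baseline <= 0:
        raise ValueError("hazard_baseline must be > 0")
    cov = cohort.covariates
    if "visit_age" not in cov.columns:
        raise ValueError("run simulate_phenotype before simulate_onset_ages")
    rng = substream(config.seed, "onset")
    g = cohort.truth["true_score"].to_numpy()
    rate = config.hazard_baseline * np.exp(config.hazard_beta_prs * g)
    onset = rng.exponential(1.0 / rate)
    visit = cov["visit_age"].to_numpy()
    event = onset <= visit
    cov["onset_age"] = np.where(event, onset, np.nan)
    cov[f"case_{config.disease}"] = event.astype(int)
    return cov


def simulate_cohort(
    specs: list[PopulationSpec],
    config: SimulationConfig,
    with_onset: bool = False,
) -> SimulatedCohort:
    """Run every generator stage and return the complete cohort.

    With ``with_onset=True`` the case column is the longitudinal
    (onset-before-visit) definition; otherwise it is the cross-sectional
    liability-threshold definition used by the logistic analyses.
    """
    cohort = simulate_study_cohort(specs, config)
    simulate_phenotype(cohort, config)
    simulate_family_history(cohort, config)
    if with_onset:
        simulate_onset_ages(cohort, config)
    return cohort
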