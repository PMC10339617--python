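"""Generator checks: frequency model moments, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aprs import io
from aprs.scoring import read_scoring_file
from aprs.simulate import (
    PopulationSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_family_history,
    simulate_onset_ages,
    simulate_phenotype,
    simulate_reference_panel,
    simulate_scoring_file,
    simulate_study_cohort,
)


class TestReferencePanel:
    def test_zero_fst_reproduces_ancestral_frequency(self):
        specs = [PopulationSpec("A", 50, fst=0.0), PopulationSpec("B", 50, fst=0.0)]
        cfg = SimulationConfig(n_variants=500, seed=1)
        panel = simulate_reference_panel(specs, cfg)
        fa = panel.variants["freq_A"].to_numpy()
        fb = panel.variants["freq_B"].to_numpy()
        assert np.array_equal(fa, fb)
        assert np.array_equal(fa, panel.variants["p_ancestral"].to_numpy())

    def test_balding_nichols_moments(self):
        # Var(p_pop | p0) = F * p0 (1 - p0); check within 3 SE over many draws
        f = 0.1
        specs = [PopulationSpec("A", 2, fst=f), PopulationSpec("B", 2, fst=f)]
        cfg = SimulationConfig(
            n_variants=4000, seed=2, ancestral_freq_range=(0.5, 0.5)
        )
        panel = simulate_reference_panel(specs, cfg)
        p = panel.variants["freq_A"].to_numpy()
        target_var = f * 0.25
        assert abs(p.mean() - 0.5) < 3 * np.sqrt(target_var / len(p))
        # SE of a variance estimate for Beta draws: use 3 * var * sqrt(2/n)
        assert abs(p.var() - target_var) < 3 * target_var * np.sqrt(2 / len(p))

    def test_genotypes_hardy_weinberg_mean(self):
        specs = [PopulationSpec("A", 3000, fst=0.0), PopulationSpec("B", 10, fst=0.0)]
        cfg = SimulationConfig(n_variants=50, seed=3)
        panel = simulate_reference_panel(specs, cfg)
        p = panel.variants["freq_A"].to_numpy()
        mask = panel.populations == "A"
        emp = panel.dosages[mask].mean(axis=0) / 2
        se = np.sqrt(p * (1 - p) / (2 * mask.sum()))
        assert (np.abs(emp - p) < 4 * se).all()

    def test_fst_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            PopulationSpec("A", 10, fst=1.0)
        with pytest.raises(ValueError, match="fst"):
            PopulationSpec("A", 10, fst=-0.1)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError, match="2 populations"):
            simulate_reference_panel(
                [PopulationSpec("A", 10)], SimulationConfig(n_variants=10, seed=0)
            )

    def test_determinism_byte_identical_vcf(self, tmp_path):
        specs = [PopulationSpec("A", 20, fst=0.1), PopulationSpec("B", 20, fst=0.2)]
        cfg = SimulationConfig(n_variants=30, seed=9)
        for name in ("a.vcf", "b.vcf"):
            io.write_vcf(simulate_reference_panel(specs, cfg), tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


class TestStudyCohort:
    def test_sample_bookkeeping(self):
        specs = [PopulationSpec("EUR", 50), PopulationSpec("SAS", 50)]
        cfg = SimulationConfig(n_variants=40, seed=4)
        cohort = simulate_study_cohort(specs, cfg)
        assert cohort.genotypes.n_samples == 100
        counts = pd.Series(cohort.genotypes.populations).value_counts()
        assert counts["EUR"] == 50 and counts["SAS"] == 50

    def test_study_and_reference_share_frequencies(self):
        specs = [PopulationSpec("A", 10), PopulationSpec("B", 10)]
        cfg = SimulationConfig(n_variants=25, seed=5)
        panel = simulate_reference_panel(specs, cfg)
        cohort = simulate_study_cohort(specs, cfg)
        pd.testing.assert_frame_equal(panel.variants, cohort.genotypes.variants)

    def test_reproducible_under_seed(self):
        specs = [PopulationSpec("A", 15), PopulationSpec("B", 15)]
        cfg = SimulationConfig(n_variants=20, seed=6)
        a = simulate_study_cohort(specs, cfg)
        b = simulate_study_cohort(specs, cfg)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)


class TestScoringFileGeneration:
    def test_ambiguous_count_deterministic(self):
        specs = [PopulationSpec("A", 5), PopulationSpec("B", 5)]
        cfg = SimulationConfig(n_variants=100, ambiguous_fraction=0.1, seed=7)
        cohort = simulate_study_cohort(specs, cfg)
        assert int(cohort.scoring.is_ambiguous().sum()) == 10

    def test_zero_sd_gives_constant_weights(self):
        specs = [PopulationSpec("A", 5), PopulationSpec("B", 5)]
        cfg = SimulationConfig(
            n_variants=50, weight_mean=0.3, weight_sd=0.0, seed=8
        )
        cohort = simulate_study_cohort(specs, cfg)
        assert np.allclose(cohort.scoring.records["effect_weight"], 0.3)

    def test_round_trip_write_parse(self, tmp_path):
        specs = [PopulationSpec("A", 5), PopulationSpec("B", 5)]
        cfg = SimulationConfig(n_variants=30, seed=9)
        cohort = simulate_study_cohort(specs, cfg)
        path = tmp_path / "scoring.txt"
        io.write_scoring_file(cohort.scoring, path)
        parsed = read_scoring_file(path)
        assert parsed.pgs_id == cohort.scoring.pgs_id
        got = parsed.records.reset_index(drop=True)
        want = cohort.scoring.records.reset_index(drop=True)
        assert list(got["variant_id"]) == list(want["variant_id"])
        assert np.allclose(got["effect_weight"], want["effect_weight"])
        assert list(got["effect_allele"]) == list(want["effect_allele"])

    def test_bad_ambiguous_fraction_rejected(self):
        with pytest.raises(ValueError, match="ambiguous_fraction"):
            SimulationConfig(n_variants=10, ambiguous_fraction=1.5)


class TestPhenotype:
    def test_prevalence_calibration_under_null_betas(self):
        specs = [PopulationSpec("A", 3000), PopulationSpec("B", 3000)]
        cfg = SimulationConfig(
            n_variants=50, seed=10, beta_prs=0, beta_sex=0, beta_age=0,
            prevalence=0.1,
        )
        cohort = simulate_study_cohort(specs, cfg)
        cov = simulate_phenotype(cohort, cfg)
        frac = cov["case_disease"].mean()
        se = np.sqrt(0.1 * 0.9 / len(cov))
        assert abs(frac - 0.1) < 3 * se

    def test_cases_have_higher_liability(self, small_cohort):
        truth = small_cohort.truth
        case = small_cohort.covariates["case_disease"].to_numpy() == 1
        assert truth.loc[case, "liability"].mean() > truth.loc[~case, "liability"].mean()

    def test_age_within_recruitment_range(self, small_cohort):
        age = small_cohort.covariates["age"]
        assert age.between(40, 69).all()

    def test_overloaded_liability_rejected(self):
        with pytest.raises(ValueError, match="residual variance"):
            SimulationConfig(n_variants=10, beta_prs=1.0).residual_variance()


class TestFamilyHistory:
    def _cohort(self, beta_prs, shared_env, prevalence=0.3, n=4000, seed=20):
        specs = [PopulationSpec("A", n // 2), PopulationSpec("B", n // 2)]
        cfg = SimulationConfig(
            n_variants=60, seed=seed, beta_prs=beta_prs, beta_sex=0.0,
            beta_age=0.0, fh_shared_env=shared_env, prevalence=prevalence,
        )
        cohort = simulate_study_cohort(specs, cfg)
        simulate_phenotype(cohort, cfg)
        simulate_family_history(cohort, cfg)
        return cohort

    @staticmethod
    def _crude_or(cov):
        case = cov["case_disease"].to_numpy()
        fh = cov["fh_disease"].to_numpy()
        a = ((case == 1) & (fh == 1)).sum()
        b = ((case == 0) & (fh == 1)).sum()
        c = ((case == 1) & (fh == 0)).sum()
        d = ((case == 0) & (fh == 0)).sum()
        return (a * d) / (b * c)

    def test_no_sharing_gives_null_fh_or(self):
        cohort = self._cohort(beta_prs=0.0, shared_env=0.0)
        or_ = self._crude_or(cohort.covariates)
        # chi-square independence test should not reject at a generous level
        tab = pd.crosstab(
            cohort.covariates["case_disease"], cohort.covariates["fh_disease"]
        )
        _, p, _, _ = stats.chi2_contingency(tab)
        assert 0.7 < or_ < 1.4
        assert p > 0.01

    def test_genetic_sharing_inflates_fh_or(self):
        cohort = self._cohort(beta_prs=0.6, shared_env=0.0, seed=21)
        assert self._crude_or(cohort.covariates) > 1.2

    def test_correlation_lifts_fh_rate_above_independence_bound(self):
        # with positively correlated relatives, P(FH) for cases exceeds the
        # independent-relative bound 1 - (1 - prevalence)^n_relatives
        cohort = self._cohort(beta_prs=0.6, shared_env=0.1, prevalence=0.5, seed=22)
        cov = cohort.covariates
        p_fh_cases = cov.loc[cov["case_disease"] == 1, "fh_disease"].mean()
        assert p_fh_cases > 1 - 0.5**3

    def test_zero_relatives_rejected(self):
        cohort = self._cohort(beta_prs=0.0, shared_env=0.0, n=200)
        cfg = SimulationConfig(n_variants=60, seed=20, n_relatives=0)
        with pytest.raises(ValueError, match="n_relatives"):
            simulate_family_history(cohort, cfg)


class TestOnsetAges:
    def test_all_early_onsets_make_everyone_a_case(self):
        specs = [PopulationSpec("A", 100), PopulationSpec("B", 100)]
        cfg = SimulationConfig(
            n_variants=30, seed=30, hazard_baseline=5.0, hazard_beta_prs=0.0
        )
        cohort = simulate_study_cohort(specs, cfg)
        simulate_phenotype(cohort, cfg)
        cov = simulate_onset_ages(cohort, cfg)
        assert (cov["case_disease"] == 1).all()
        assert (cov["onset_age"] <= cov["visit_age"]).all()

    def test_event_indicator_consistent_with_case(self):
        specs = [PopulationSpec("A", 500), PopulationSpec("B", 500)]
        cfg = SimulationConfig(n_variants=30, seed=31)
        cohort = simulate_cohort(specs, cfg, with_onset=True)
        cov = cohort.covariates
        has_onset = cov["onset_age"].notna()
        assert (cov["case_disease"] == has_onset.astype(int)).all()

    def test_bad_baseline_rejected(self):
        specs = [PopulationSpec("A", 10), PopulationSpec("B", 10)]
        cfg = SimulationConfig(n_variants=10, seed=32)
        cohort = simulate_study_cohort(specs, cfg)
        simulate_phenotype(cohort, cfg)
        bad = SimulationConfig(n_variants=10, seed=32, hazard_baseline=0.0)
        with pytest.raises(ValueError, match="hazard_baseline"):
            simulate_onset_ages(cohort, bad)


class TestGenotypeIO:
    def test_vcf_round_trip(self, tmp_path):
        specs = [PopulationSpec("A", 12), PopulationSpec("B", 8)]
        cfg = SimulationConfig(n_variants=15, seed=40)
        panel = simulate_reference_panel(specs, cfg)
        path = tmp_path / "panel.vcf"
        io.write_vcf(panel, path)
        back = io.read_vcf(path)
        assert back.samples == panel.samples
        assert np.array_equal(back.dosages, panel.dosages)
        assert list(back.variants["ref"]) == list(panel.variants["ref"])

    def test_dosage_matrix_round_trip(self, tmp_path):
        specs = [PopulationSpec("A", 6), PopulationSpec("B", 6)]
        cfg = SimulationConfig(n_variants=9, seed=41)
        panel = simulate_reference_panel(specs, cfg)
        path = tmp_path / "dosages.tsv"
        io.write_dosage_matrix(panel, path)
        back = io.read_dosage_matrix(path)
        assert np.allclose(back.to_numpy(), panel.dosages)
        assert list(back.columns) == list(panel.variants["variant_id"])
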