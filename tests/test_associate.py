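"""Logistic models, odds ratios, splits, and discrimination metrics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from aprs.associate import (
    crude_or_2x2,
    downsample_to_ratio,
    evaluate_discrimination,
    fit_fh_joint_model,
    fit_group_model,
    fit_logistic,
    interaction_lr_test,
    split_train_test,
)
from aprs.stratify import joint_fh_groups
from conftest import logistic_sample


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        fit = fit_logistic(y, pd.DataFrame(index=range(100)))
        assert fit.terms["estimate"].iloc[0] == pytest.approx(np.log(30 / 70), abs=1e-6)

    def test_two_by_two_table_or_exact(self):
        # exposed: 100 cases / 50 controls; unexposed: 100 cases / 100 controls
        y = np.array([1] * 100 + [0] * 50 + [1] * 100 + [0] * 100)
        x = np.array([1.0] * 150 + [0.0] * 200)
        fit = fit_logistic(y, pd.DataFrame({"exposed": x}))
        or_, lo, hi = fit.odds_ratio("exposed")
        assert or_ == pytest.approx(2.0, abs=1e-6)
        assert lo < 2.0 < hi

    def test_parameter_recovery(self, rng):
        n = 20_000
        design = pd.DataFrame({"aprs": rng.normal(size=n)})
        y = logistic_sample(rng, n, [-2.0, 0.5], design)
        fit = fit_logistic(y, design)
        est = fit.terms.set_index("term").loc["aprs", "estimate"]
        assert abs(est - 0.5) < 0.05

    def test_complete_separation_names_column(self):
        y = np.array([0] * 10 + [1] * 10)
        design = pd.DataFrame(
            {"ok": np.random.default_rng(0).normal(size=20), "sep": y.astype(float)}
        )
        with pytest.raises(ValueError, match="sep"):
            fit_logistic(y, design)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_logistic(np.array([0, 1, 2] * 4), pd.DataFrame(index=range(12)))


class TestGroupModels:
    @staticmethod
    def _expected_count_data(penetrance, n_per_group=4000):
        """Deterministic expected-count dataset: per group, exactly
        round(p * n) cases."""
        rows = []
        for grp, p in penetrance.items():
            k = int(round(p * n_per_group))
            rows += [(grp, 1)] * k + [(grp, 0)] * (n_per_group - k)
        return pd.DataFrame(rows, columns=["group", "y"])

    def test_closed_form_odds_from_constructed_table(self):
        df = self._expected_count_data(
            {"low": 0.1, "intermediate": 0.2, "high": 0.4}
        )
        fit = fit_group_model(df["y"], df["group"])
        or_low, *_ = fit.odds_ratio("low")
        or_high, *_ = fit.odds_ratio("high")
        assert or_low == pytest.approx((0.1 / 0.9) / (0.2 / 0.8), abs=1e-6)
        assert or_high == pytest.approx((0.4 / 0.6) / (0.2 / 0.8), abs=1e-6)

    def test_null_groups_cover_one(self, rng):
        n = 3000
        groups = rng.choice(["low", "intermediate", "high"], size=n, p=[0.2, 0.6, 0.2])
        y = (rng.random(n) < 0.2).astype(int)
        fit = fit_group_model(y, groups)
        for term in ("low", "high"):
            _, lo, hi = fit.odds_ratio(term)
            assert lo < 1.0 < hi

    def test_empty_level_rejected(self):
        df = self._expected_count_data({"low": 0.1, "intermediate": 0.2}, 100)
        with pytest.raises(ValueError, match="high"):
            fit_group_model(df["y"], df["group"])

    def test_joint_model_exact_recovery_from_cell_odds(self):
        # saturated oracle: six cells with chosen penetrances; each dummy's
        # OR equals its cell odds over the reference-cell odds
        pen = {
            "low_fh_neg": 0.10,
            "low_fh_pos": 0.15,
            "intermediate_fh_neg": 0.20,
            "intermediate_fh_pos": 0.28,
            "high_fh_neg": 0.35,
            "high_fh_pos": 0.50,
        }
        df = self._expected_count_data(pen)
        fit = fit_fh_joint_model(df["y"], df["group"])
        ref_odds = 0.20 / 0.80
        for cell, p in pen.items():
            if cell == "intermediate_fh_neg":
                continue
            or_, *_ = fit.odds_ratio(cell)
            assert or_ == pytest.approx((p / (1 - p)) / ref_odds, rel=1e-5)

    def test_empty_joint_cell_dropped_with_warning(self, rng):
        n = 600
        groups = rng.choice(["low", "intermediate", "high"], size=n)
        fh = np.zeros(n)  # no positive FH at all -> three empty cells
        joint = joint_fh_groups(groups, fh)
        y = (rng.random(n) < 0.3).astype(int)
        with pytest.warns(UserWarning, match="empty group level"):
            fit = fit_fh_joint_model(y, joint)
        assert "low_fh_pos" not in set(fit.terms["term"])

    def test_multiplicative_truth_gives_null_interaction(self, rng):
        # independent FH and group effects on the logit scale: the joint OR
        # is the product of the marginals and the LR interaction test is null
        n = 20_000
        groups = rng.choice(["low", "intermediate", "high"], size=n, p=[0.2, 0.6, 0.2])
        fh = rng.integers(0, 2, n)
        lp = (
            -1.5
            + 0.5 * (groups == "high")
            - 0.5 * (groups == "low")
            + 0.7 * fh
        )
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        joint = joint_fh_groups(groups, fh)
        fit = fit_fh_joint_model(y, joint)
        or_joint, *_ = fit.odds_ratio("high_fh_pos")
        assert or_joint == pytest.approx(np.exp(0.5 + 0.7), rel=0.15)
        _, p, df_ = interaction_lr_test(y, groups, fh)
        assert df_ == 2
        assert p > 0.01


class TestCrudeOr:
    def test_family_history_style_counts(self):
        # case/control FH counts arranged as (exposed cases, exposed
        # controls, unexposed cases, unexposed controls)
        or_, (lo, hi), flag = crude_or_2x2(457, 3193, 365, 4649)
        assert or_ == pytest.approx(457 * 4649 / (3193 * 365), rel=1e-12)
        assert or_ == pytest.approx(1.823, abs=0.001)
        assert not flag

    def test_balanced_table_symmetric_ci(self):
        or_, (lo, hi), _ = crude_or_2x2(10, 10, 10, 10)
        assert or_ == 1.0
        assert np.log(hi) == pytest.approx(-np.log(lo), abs=1e-12)

    def test_zero_cell_correction_flagged(self):
        or_, _, flag = crude_or_2x2(1, 0, 5, 5)
        assert flag
        assert np.isfinite(or_)

    def test_double_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            crude_or_2x2(0, 0, 5, 5)


class TestSplitAndDownsample:
    def test_sizes_75_25(self, rng):
        table = pd.DataFrame({"y": rng.integers(0, 2, 100)})
        tr, te = split_train_test(table, "y", seed=4)
        assert len(tr) == 75 and len(te) == 25
        assert len(set(tr) & set(te)) == 0

    def test_same_seed_same_split(self, rng):
        table = pd.DataFrame({"y": rng.integers(0, 2, 80)})
        a = split_train_test(table, "y", seed=9)
        b = split_train_test(table, "y", seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_all_controls_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            split_train_test(pd.DataFrame({"y": [0] * 20}), "y")

    def test_downsample_halves_cases(self, rng):
        y = np.array([1] * 200 + [0] * 800)
        table = pd.DataFrame({"y": y})
        out = downsample_to_ratio(table, "y", target_ratio=1 / 8, seed=2)
        assert out["y"].sum() == 100
        assert (out["y"] == 0).sum() == 800

    def test_target_equal_to_current_is_identity(self):
        table = pd.DataFrame({"y": [1] * 100 + [0] * 400})
        out = downsample_to_ratio(table, "y", target_ratio=0.25, seed=3)
        assert len(out) == 500

    def test_same_seed_same_subsample(self, rng):
        table = pd.DataFrame({"y": np.array([1] * 300 + [0] * 300), "i": range(600)})
        a = downsample_to_ratio(table, "y", 0.5, seed=5)
        b = downsample_to_ratio(table, "y", 0.5, seed=5)
        assert a["i"].tolist() == b["i"].tolist()


class TestDiscrimination:
    def test_perfect_separation_max_scores(self):
        y = np.array([0, 0, 1, 1])
        res = evaluate_discrimination(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert res.auroc == 1.0
        assert res.auprc == 1.0

    def test_four_point_pair_counting_example(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8])
        res = evaluate_discrimination(y, s)
        assert res.auroc == pytest.approx(0.75)

    def test_random_scores_near_half_and_prevalence(self, rng):
        n = 20_000
        y = rng.integers(0, 2, n)
        s = rng.random(n)
        res = evaluate_discrimination(y, s)
        assert abs(res.auroc - 0.5) < 0.02
        assert abs(res.auprc - y.mean()) < 0.02

    def test_matches_sklearn_rank_auc(self, rng):
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500).round(1)  # force ties
        res = evaluate_discrimination(y, s)
        assert res.auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_discrimination(np.ones(10), np.random.rand(10))

    def test_delong_ci_covers_reasonably(self, rng):
        # coverage of the DeLong CI for a known-AUC Gaussian shift model
        shift = 1.0
        import math

        true_auc = 0.5 * (1 + math.erf(shift / 2))  # Phi(shift / sqrt 2)
        hits = 0
        for _ in range(100):
            s = np.concatenate([rng.normal(size=150), rng.normal(shift, 1, 150)])
            y = np.array([0] * 150 + [1] * 150)
            res = evaluate_discrimination(y, s)
            if res.auroc_ci[0] <= true_auc <= res.auroc_ci[1]:
                hits += 1
        assert hits >= 85
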