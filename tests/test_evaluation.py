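"""Performance measures, permutation test mechanics, replicate
aggregation, Wilcoxon variant, multimodal gate, overfitting diagnostic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import armsml
from armsml import cv, evaluation
from armsml.types import (BootstrapReport, ClassifierSpec, FoldPrediction,
                          PerformanceReport)
from conftest import balanced_pair_cohort


def _preds(tp, fn, tn, fp):
    out = []
    i = 0
    for true, pred, n in (("T", "T", tp), ("T", "NT", fn),
                          ("NT", "NT", tn), ("NT", "T", fp)):
        for _ in range(n):
            out.append(FoldPrediction(f"s{i}", true, pred, 0.0, {}, 0))
            i += 1
    return out


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        r = evaluation.confusion_metrics(_preds(14, 9, 16, 7))
        assert r.SE == pytest.approx(0.609, abs=5e-4)
        assert r.SP == pytest.approx(0.696, abs=5e-4)
        assert r.BAC == pytest.approx(0.652, abs=5e-4)
        assert r.PLR == pytest.approx(2.000, abs=5e-4)
        assert r.NLR == pytest.approx(0.562, abs=5e-4)
        assert r.DOR == pytest.approx(3.556, abs=5e-4)

    def test_perfect_prediction_yields_infinite_plr(self):
        r = evaluation.confusion_metrics(_preds(10, 0, 10, 0))
        assert r.SE == r.SP == r.BAC == 1.0
        assert r.NLR == 0.0
        assert math.isinf(r.PLR)
        assert math.isinf(r.DOR)

    def test_all_predicted_negative_on_balanced_data(self):
        r = evaluation.confusion_metrics(_preds(0, 10, 10, 0))
        assert r.SE == 0.0 and r.SP == 1.0 and r.BAC == 0.5

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluation.confusion_metrics(_preds(5, 5, 0, 0))

    @given(st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_metric_identities_hold(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        r = evaluation.confusion_metrics(_preds(tp, fn, tn, fp))
        assert r.BAC == pytest.approx((r.SE + r.SP) / 2, abs=1e-12)
        assert (r.TP, r.FN, r.TN, r.FP) == (tp, fn, tn, fp)
        if r.SP < 1:
            assert r.PLR == pytest.approx(r.SE / (1 - r.SP), abs=1e-12)
        if r.SP > 0:
            assert r.NLR == pytest.approx((1 - r.SE) / r.SP, abs=1e-12)
        if np.isfinite(r.PLR) and np.isfinite(r.NLR) and r.NLR > 0:
            assert r.DOR == pytest.approx(r.PLR / r.NLR, abs=1e-9)


class TestPermutationTest:
    def test_constant_score_p_is_one(self):
        """A constant score has chance BAC under every permutation, so the
        add-one estimator returns exactly 1."""
        cohort, ss = balanced_pair_cohort(10, seed=1)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(1.0, index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=1, by_protocol=False)
        res = evaluation.permutation_test_bac(
            ClassifierSpec("logistic"), plan, score.to_frame(), labels,
            n_permutations=50, seed=1, simple_logistic=True)
        assert res.observed_bac == 0.5
        assert res.p_value == 1.0

    def test_strong_signal_p_is_minimum(self):
        cohort, ss = balanced_pair_cohort(10, seed=2)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(np.where(labels == "T", 5.0, -5.0)
                          + np.random.default_rng(2).normal(0, 0.1, 20),
                          index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=2, by_protocol=False)
        res = evaluation.permutation_test_bac(
            ClassifierSpec("logistic"), plan, score.to_frame(), labels,
            n_permutations=99, seed=2, simple_logistic=True)
        assert res.observed_bac == 1.0
        # add-one formula with no null reaching the observed BAC
        hits = int((res.null_bacs >= res.observed_bac - 1e-12).sum())
        assert res.p_value == pytest.approx((1 + hits) / 100)
        assert res.p_value <= 0.05

    def test_add_one_formula_consistency(self):
        cohort, ss = balanced_pair_cohort(8, seed=3)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(np.random.default_rng(3).normal(size=16),
                          index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=3, by_protocol=False)
        res = evaluation.permutation_test_bac(
            ClassifierSpec("logistic"), plan, score.to_frame(), labels,
            n_permutations=40, seed=3, simple_logistic=True)
        hits = int((res.null_bacs >= res.observed_bac - 1e-12).sum())
        assert res.p_value == pytest.approx((1 + hits) / 41)
        assert 0 < res.p_value <= 1

    def test_nested_svm_permutation_path_runs(self):
        cohort, ss = balanced_pair_cohort(8, seed=4)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        rng = np.random.default_rng(4)
        feats = pd.DataFrame(rng.normal(size=(16, 5)),
                             index=labels.index,
                             columns=[f"f{j}" for j in range(5)])
        plan = cv.build_lpo_plan(ss, cohort, seed=4, by_protocol=False)
        spec = ClassifierSpec("linear_svm", svm_C=(0.1, 1.0))
        res = evaluation.permutation_test_bac(spec, plan, feats, labels,
                                              n_permutations=20, seed=4)
        assert 0 < res.p_value <= 1
        assert len(res.null_bacs) == 20


class TestAggregateBootstraps:
    def test_three_of_five_rule(self):
        decision, count = evaluation.aggregate_bootstraps(
            [0.01, 0.04, 0.049, 0.2, 0.6])
        assert count == 3 and decision is True

    def test_no_significant_replicates(self):
        decision, count = evaluation.aggregate_bootstraps([0.06] * 5)
        assert count == 0 and decision is False

    def test_threshold_is_ceil_of_fraction(self):
        # 5 replicates at 60 % -> 3 needed
        decision, _ = evaluation.aggregate_bootstraps(
            [0.01, 0.01, 0.2, 0.2, 0.2])
        assert decision is False  # only 2 < alpha
        decision, _ = evaluation.aggregate_bootstraps(
            [0.01, 0.01, 0.01, 0.2, 0.2])
        assert decision is True

    def test_monotone_in_p_values(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = list(rng.uniform(0, 1, 5))
            base, _ = evaluation.aggregate_bootstraps(p)
            lowered = [x * rng.uniform(0, 1) for x in p]
            better, _ = evaluation.aggregate_bootstraps(lowered)
            assert better or not base  # lowering p never flips true->false

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluation.aggregate_bootstraps([])


class TestWilcoxonMedianBac:
    def test_all_above_chance_n5(self):
        res = evaluation.wilcoxon_median_bac([0.60, 0.62, 0.58, 0.61, 0.59])
        assert res.p_value == pytest.approx(1 / 32)

    def test_all_below_chance(self):
        res = evaluation.wilcoxon_median_bac([0.40, 0.45, 0.42, 0.48, 0.41])
        assert res.p_value == 1.0

    def test_values_at_chance_dropped(self):
        res = evaluation.wilcoxon_median_bac([0.5, 0.5, 0.6, 0.7, 0.65])
        ref = evaluation.wilcoxon_median_bac([0.6, 0.7, 0.65])
        assert res.p_value == ref.p_value

    @given(st.lists(st.floats(0.05, 0.95, allow_nan=False),
                    min_size=5, max_size=8))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_scipy_exact_when_tie_free(self, bacs):
        d = np.asarray(bacs) - 0.5
        d = d[d != 0]
        if len(d) < 2 or len(np.unique(np.abs(d))) < len(d):
            return
        ours = evaluation.wilcoxon_median_bac(bacs)
        ref = sps.wilcoxon(d, alternative="greater", method="exact").pvalue
        assert ours.p_value == pytest.approx(ref, abs=1e-9)


class TestMultimodalGate:
    def _report(self, modality, decision):
        return BootstrapReport(modality, "cfg", [], [], [], 0, decision)

    def test_no_modality_admitted_means_no_multimodal_model(self):
        reports = [self._report(m, False)
                   for m in ("smri", "genetic", "environmental")]
        assert evaluation.multimodal_gate(reports) == []

    def test_single_admission(self):
        reports = [self._report("smri", False), self._report("genetic", True)]
        assert evaluation.multimodal_gate(reports) == ["genetic"]

    def test_all_admitted(self):
        reports = [self._report(m, True) for m in ("a", "b")]
        assert evaluation.multimodal_gate(reports) == ["a", "b"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluation.multimodal_gate([])


class TestOverfittingReport:
    def test_identical_bacs_gap_zero(self):
        rep = evaluation.overfitting_report([0.6, 0.7, 0.8], [0.6, 0.7, 0.8])
        assert rep["mean_gap"] == 0.0

    def test_known_gap(self):
        rep = evaluation.overfitting_report([1.0] * 5, [0.5] * 5)
        assert rep["mean_gap"] == pytest.approx(0.5)
        assert rep["ci_low"] == pytest.approx(0.5)

    def test_null_svm_runs_show_resubstitution_optimism(self):
        """On pure-noise data the flexible SVM memorizes its training set:
        train BAC systematically exceeds out-of-fold BAC."""
        from conftest import balanced_pair_cohort
        train_bacs, test_bacs = [], []
        for s in range(4):
            cohort, ss = balanced_pair_cohort(12, seed=40 + s)
            labels = cohort.phenotypes.set_index("subject_id")["transition"]
            rng = np.random.default_rng(50 + s)
            feats = pd.DataFrame(rng.normal(size=(24, 30)),
                                 index=labels.index,
                                 columns=[f"f{j}" for j in range(30)])
            plan = cv.build_lpo_plan(ss, cohort, seed=s, by_protocol=False)
            spec = ClassifierSpec("linear_svm",
                                  svm_C=cv.default_grids().svm_C)
            res = armsml.run_nested_cv(spec, plan, feats, labels)
            train_bacs.append(res.mean_train_bac)
            test_bacs.append(res.bac)
        rep = evaluation.overfitting_report(train_bacs, test_bacs)
        assert rep["mean_gap"] > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluation.overfitting_report([0.5], [0.5, 0.6])


class TestSummarizeReplicates:
    def test_published_table_layout(self):
        reports = [evaluation.confusion_metrics(_preds(14, 9, 16, 7)),
                   evaluation.confusion_metrics(_preds(12, 11, 15, 8))]
        table = evaluation.summarize_replicates(reports, [0.02, 0.3])
        assert list(table.index) == ["SE (%)", "SP (%)", "BAC (%)", "PLR",
                                     "NLR", "DOR", "Significant models"]
        assert table.loc["Significant models", "value"] == "1"
        assert "±" in table.loc["BAC (%)", "value"]
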