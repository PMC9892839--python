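"""Classifier engine: solver correctness against sklearn, nested-CV
contracts, leakage canaries, and the single-score logistic path."""

import numpy as np
import pandas as pd
import pytest

import armsml
from armsml import cv, models
from armsml._solvers import logistic_newton, svm_dual_cd
from armsml.types import ClassifierSpec, CVFold
from conftest import balanced_pair_cohort


def _features_frame(x, ids):
    return pd.DataFrame(x, index=pd.Index(ids, name="subject_id"),
                        columns=[f"f{j}" for j in range(x.shape[1])])


def _svm_spec():
    return ClassifierSpec("linear_svm", svm_C=cv.default_grids().svm_C)


class TestSolvers:
    """The in-house solvers against their sklearn counterparts (the
    independent route; sklearn is never used in the pipeline's hot path)."""

    @pytest.mark.parametrize("C", [2 ** -5, 0.5, 2.0, 2 ** 4])
    def test_svm_dual_cd_matches_linear_svc(self, C):
        from sklearn.svm import LinearSVC
        rng = np.random.default_rng(42)
        x = rng.normal(size=(36, 20))
        y = np.sign(rng.normal(size=36))
        xb = np.hstack([x, np.ones((36, 1))])
        w_ours = svm_dual_cd(xb, y, C, 20000, 1e-10)
        ref = LinearSVC(C=C, loss="hinge", max_iter=500_000, tol=1e-10)
        ref.fit(x, y)
        w_ref = np.append(ref.coef_.ravel(), ref.intercept_)
        assert np.allclose(w_ours, w_ref, atol=1e-6)

    def test_logistic_newton_matches_sklearn(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(7)
        x = rng.normal(size=(60, 3))
        y = (x @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=60) > 0)
        xb = np.hstack([x, np.ones((60, 1))])
        beta = logistic_newton(xb, y.astype(np.float64))
        ref = LogisticRegression(C=np.inf, max_iter=10_000, tol=1e-12)
        ref.fit(x, y)
        w_ref = np.append(ref.coef_.ravel(), ref.intercept_)
        assert np.allclose(beta, w_ref, atol=1e-5)

    def test_separable_logistic_stays_finite(self):
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        xb = np.hstack([x, np.ones((4, 1))])
        beta = logistic_newton(xb, y)
        assert np.all(np.isfinite(beta))
        # predictions at the ML limit: threshold between the classes
        p = 1 / (1 + np.exp(-(xb @ beta)))
        assert (p[:2] < 0.5).all() and (p[2:] > 0.5).all()

    def test_svm_decision_values_monotone_in_margin_distance(self):
        # 2-D data with a known separating direction
        x = np.array([[-2.0, 0], [-1, 0], [1, 0], [2, 0], [3, 0]])
        y = np.array([-1.0, -1, 1, 1, 1])
        xb = np.hstack([x, np.ones((5, 1))])
        w = svm_dual_cd(xb, y, 10.0, 20000, 1e-10)
        dv = xb @ w
        assert np.all(np.diff(dv) > 0)  # monotone along the x-axis


class TestElasticNet:
    def test_l1_zero_small_lambda_approaches_unpenalized(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(200, 5))
        y_pos = (x @ np.array([0.8, -0.5, 0.3, 0.0, 0.2])
                 + rng.normal(size=200) > 0)
        enet = models._fit_one("elastic_net", {"l1": 0.0, "lambda": 1e-6},
                               x, y_pos, 0.5)
        logit = models._fit_one("logistic", {}, x, y_pos, 0.5)
        assert np.allclose(enet.w, logit.w, atol=1e-2)

    def test_huge_lambda_shrinks_coefficients_to_zero(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(50, 4))
        y_pos = rng.random(50) > 0.5
        enet = models._fit_one("elastic_net", {"l1": 1.0, "lambda": 50.0},
                               x, y_pos, 0.5)
        assert np.allclose(enet.w[:-1], 0.0, atol=1e-6)


class TestNestedCV:
    def test_separable_classes_reach_perfect_bac(self):
        cohort, ss = balanced_pair_cohort(20, seed=1)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 10))
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        x[:, 0] += np.where(labels.loc[cohort.subject_ids] == "T", 4.0, 0.0)
        feats = _features_frame(x, cohort.subject_ids)
        plan = cv.build_lpo_plan(ss, cohort, seed=2, by_protocol=False)
        res = armsml.run_nested_cv(_svm_spec(), plan, feats, labels)
        assert res.bac == 1.0

    def test_noise_features_bac_near_chance(self):
        bacs = []
        for s in range(6):
            cohort, ss = balanced_pair_cohort(20, seed=100 + s)
            rng = np.random.default_rng(200 + s)
            feats = _features_frame(rng.normal(size=(40, 10)),
                                    cohort.subject_ids)
            labels = cohort.phenotypes.set_index("subject_id")["transition"]
            plan = cv.build_lpo_plan(ss, cohort, seed=s, by_protocol=False)
            bacs.append(armsml.run_nested_cv(_svm_spec(), plan, feats,
                                             labels).bac)
        assert abs(np.mean(bacs) - 0.5) < 0.15

    def test_one_prediction_per_subject(self, smri_cohort, balanced,
                                        labels_of):
        rng = np.random.default_rng(5)
        feats = _features_frame(rng.normal(size=(46, 8)),
                                balanced.subject_ids)
        plan = cv.build_lpo_plan(balanced, smri_cohort, seed=5)
        res = armsml.run_nested_cv(_svm_spec(), plan, feats,
                                   labels_of(smri_cohort))
        assert len(res.predictions) == 46
        assert len({p.subject_id for p in res.predictions}) == 46

    def test_deterministic_given_inputs(self, smri_cohort, balanced,
                                        labels_of):
        rng = np.random.default_rng(6)
        feats = _features_frame(rng.normal(size=(46, 8)),
                                balanced.subject_ids)
        plan = cv.build_lpo_plan(balanced, smri_cohort, seed=6)
        r1 = armsml.run_nested_cv(_svm_spec(), plan, feats,
                                  labels_of(smri_cohort))
        r2 = armsml.run_nested_cv(_svm_spec(), plan, feats,
                                  labels_of(smri_cohort))
        pd.testing.assert_frame_equal(r1.frame(), r2.frame())

    def test_subject_mismatch_rejected(self, smri_cohort, balanced,
                                       labels_of):
        rng = np.random.default_rng(7)
        feats = _features_frame(rng.normal(size=(10, 4)),
                                balanced.subject_ids[:10])
        plan = cv.build_lpo_plan(balanced, smri_cohort, seed=7)
        with pytest.raises(ValueError, match="missing from features"):
            armsml.run_nested_cv(_svm_spec(), plan, feats,
                                 labels_of(smri_cohort))

    def test_hyperparameter_tie_break_prefers_smallest_c(self):
        """On constant features every C ties at BAC 0.5; the chosen C must
        be the grid minimum."""
        cohort, ss = balanced_pair_cohort(10, seed=8)
        feats = _features_frame(np.ones((20, 3)), cohort.subject_ids)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        plan = cv.build_lpo_plan(ss, cohort, seed=8, by_protocol=False)
        res = armsml.run_nested_cv(_svm_spec(), plan, feats, labels)
        assert all(p.chosen_hyperparameters["C"] == pytest.approx(2 ** -5)
                   for p in res.predictions)

    def test_outer_test_rows_cannot_influence_fit(self):
        """Leakage canary: making the held-out rows perfectly informative
        must not change the fitted model or its training behavior."""
        cohort, ss = balanced_pair_cohort(12, seed=9)
        rng = np.random.default_rng(9)
        x = rng.normal(size=(24, 6))
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        plan = cv.build_lpo_plan(ss, cohort, seed=9, by_protocol=False)
        fold = plan.folds[0]
        feats_clean = _features_frame(x, cohort.subject_ids)
        x_poisoned = x.copy()
        rows = [cohort.subject_ids.index(s) for s in fold.test_ids]
        for r in rows:
            x_poisoned[r] = 50.0 if labels.iloc[r] == "T" else -50.0
        feats_poisoned = _features_frame(x_poisoned, cohort.subject_ids)
        p_clean, tb_clean = models.fit_predict_fold(
            _svm_spec(), fold, feats_clean, labels)
        p_poison, tb_poison = models.fit_predict_fold(
            _svm_spec(), fold, feats_poisoned, labels)
        assert tb_clean == tb_poison
        assert (p_clean[0].chosen_hyperparameters
                == p_poison[0].chosen_hyperparameters)

    def test_single_class_training_set_rejected(self):
        cohort, ss = balanced_pair_cohort(5, seed=10)
        feats = _features_frame(np.random.default_rng(0).normal(size=(10, 3)),
                                cohort.subject_ids)
        t_ids = cohort.ids_of("T")
        nt_ids = cohort.ids_of("NT")
        fold = CVFold(0, t_ids[1:], [t_ids[0], nt_ids[0]],
                      [(t_ids[1:3], t_ids[3:])])
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        with pytest.raises(ValueError, match="single-class"):
            models.fit_predict_fold(_svm_spec(), fold, feats, labels)


class TestSimpleLpoLogistic:
    def test_perfectly_separated_score(self):
        cohort, ss = balanced_pair_cohort(8, seed=11)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(np.where(labels == "T", 3.0, -3.0),
                          index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=11, by_protocol=False)
        res = armsml.fit_simple_lpo_logistic(score, labels, plan)
        assert res.bac == 1.0

    def test_constant_score_gives_chance_bac(self):
        """An intercept-only fit on balanced data predicts the probability
        0.5 everywhere, which the strict >0.5 threshold maps to NT."""
        cohort, ss = balanced_pair_cohort(8, seed=12)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(1.0, index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=12, by_protocol=False)
        res = armsml.fit_simple_lpo_logistic(score, labels, plan)
        assert res.bac == 0.5
        assert all(p.predicted_label == "NT" for p in res.predictions)

    def test_23_pairs_give_46_predictions(self):
        cohort, ss = balanced_pair_cohort(23, seed=13)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(np.random.default_rng(13).normal(size=46),
                          index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=13, by_protocol=False)
        res = armsml.fit_simple_lpo_logistic(score, labels, plan)
        assert len(plan.folds) == 23
        assert len(res.predictions) == 46

    def test_multifeature_input_rejected(self):
        cohort, ss = balanced_pair_cohort(4, seed=14)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        plan = cv.build_lpo_plan(ss, cohort, seed=14, by_protocol=False)
        two_cols = pd.DataFrame({"a": np.zeros(8), "b": np.zeros(8)},
                                index=labels.index)
        with pytest.raises(ValueError, match="one feature"):
            armsml.fit_simple_lpo_logistic(two_cols, labels, plan)

    def test_batched_bac_matches_object_path(self):
        cohort, ss = balanced_pair_cohort(15, seed=15)
        labels = cohort.phenotypes.set_index("subject_id")["transition"]
        score = pd.Series(np.random.default_rng(15).normal(size=30),
                          index=labels.index)
        plan = cv.build_lpo_plan(ss, cohort, seed=15, by_protocol=False)
        res = armsml.fit_simple_lpo_logistic(score, labels, plan)
        tr_idx, te_idx = models.plan_index_arrays(plan, score.index)
        bac = models.simple_lpo_bac(score.to_numpy(),
                                    (labels.loc[score.index] == "T").to_numpy(),
                                    tr_idx, te_idx)
        assert bac == pytest.approx(res.bac, abs=1e-12)
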