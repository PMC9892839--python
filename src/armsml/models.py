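"""Classifier contracts and the nested cross-validation execution engine.

Three classifier families are supported: a linear soft-margin SVM (the
sMRI models), unpenalized logistic regression (single-score models:
polygenic and environmental risk score), and elastic-net-penalized
logistic regression (SNP, eQTL-score and individual-exposure models,
glmnet parameterization: mixing ratio ``l1`` and penalty strength
``lambda``).

Hyperparameters are tuned in the inner cross-validation cycle by mean
balanced accuracy over the inner validation folds; the winner (ties broken
deterministically: smallest C, then largest lambda, then smallest l1) is
refit on the full outer-train set and evaluated on the outer-test set.
All feature preparation (min-max scaling, robust PCA, forward selection)
is fit inside the training partition it serves.

Implementation note: label-independent preparation (row indexing, min-max,
PCA) is compiled once per plan and reused across label assignments — this
is what makes permutation testing with a full nested-CV re-run per
permutation affordable. Greedy forward selection depends on the labels, so
that path is recomputed per assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._solvers import logistic_newton, svm_dual_cd, svm_dual_cd_path
from .features import greedy_forward_select, minmax_fit_apply, robust_pca_reduce
from .types import ClassifierSpec, CVFold, CVPlan, FoldPrediction

__all__ = [
    "PrepRecipe",
    "NestedCVResult",
    "fit_predict_fold",
    "run_nested_cv",
    "fit_simple_lpo_logistic",
    "balanced_accuracy",
]


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(sensitivity + specificity) / 2 with T as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == "T"
    neg = ~pos
    se = float((y_pred[pos] == "T").mean()) if pos.any() else 0.0
    sp = float((y_pred[neg] == "NT").mean()) if neg.any() else 0.0
    return 0.5 * (se + sp)


def _bac_bool(y_pos: np.ndarray, pred_pos: np.ndarray) -> float:
    """Balanced accuracy on boolean is-positive arrays (hot path)."""
    pos = y_pos
    neg = ~y_pos
    se = float(pred_pos[pos].mean()) if pos.any() else 0.0
    sp = float((~pred_pos[neg]).mean()) if neg.any() else 0.0
    return 0.5 * (se + sp)


@dataclass(frozen=True)
class PrepRecipe:
    """Feature preparation declared up front, fit per training partition.

    ``minmax`` — scale each feature to [0, 1] on the training rows;
    ``pca`` — robust PCA (voxel families), capped at half the training
    size; ``forward_selection`` — greedy selection on the inner cycle
    (regional families).
    """

    minmax: bool = True
    pca: bool = False
    variance_target: float = 0.8
    forward_selection: bool = False
    retain_fraction: float = 0.1


class _LinearModel:
    """Fitted linear decision rule over a prepared feature matrix."""

    def __init__(self, w: np.ndarray, probabilistic: bool,
                 threshold: float = 0.5) -> None:
        self.w = w
        self.probabilistic = probabilistic
        self.threshold = threshold

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        eta = x @ self.w[:-1] + self.w[-1]
        if self.probabilistic:
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return eta

    def predict_pos(self, x: np.ndarray) -> np.ndarray:
        dv = self.decision_values(x)
        cut = self.threshold if self.probabilistic else 0.0
        return dv > cut

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.predict_pos(x), "T", "NT")


def _fit_one(kind: str, params: Dict[str, float], x: np.ndarray,
             y_pos: np.ndarray, threshold: float) -> _LinearModel:
    """Fit one classifier on a prepared matrix; y_pos is boolean is-T."""
    xb = np.ascontiguousarray(np.hstack([x, np.ones((x.shape[0], 1))]))
    if kind == "linear_svm":
        w = svm_dual_cd(xb, np.where(y_pos, 1.0, -1.0), float(params["C"]))
        return _LinearModel(w, probabilistic=False)
    y01 = y_pos.astype(np.float64)
    if kind == "logistic":
        w = logistic_newton(xb, y01)
        return _LinearModel(w, probabilistic=True, threshold=threshold)
    if kind == "elastic_net":
        from sklearn.linear_model import LogisticRegression
        lam, l1 = float(params["lambda"]), float(params["l1"])
        n = x.shape[0]
        clf = LogisticRegression(
            solver="saga", l1_ratio=l1,
            C=1.0 / max(n * lam, 1e-12), max_iter=5000, tol=1e-6)
        clf.fit(x, y01)
        w = np.append(clf.coef_.ravel(), clf.intercept_)
        return _LinearModel(w, probabilistic=True, threshold=threshold)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _grid_of(spec: ClassifierSpec) -> List[Dict[str, float]]:
    if spec.kind == "linear_svm":
        return [{"C": c} for c in spec.svm_C] or [{"C": 1.0}]
    if spec.kind == "elastic_net":
        grid = [{"l1": a, "lambda": lam}
                for a in spec.enet_l1 for lam in spec.enet_lambda]
        return grid or [{"l1": 0.5, "lambda": 0.1}]
    return [{}]  # unpenalized logistic has no hyperparameters


def _tie_break_key(params: Dict[str, float]) -> tuple:
    # smaller C preferred, then larger lambda, then smaller l1
    return (params.get("C", 0.0), -params.get("lambda", 0.0),
            params.get("l1", 0.0))


def _prepare(train_x: np.ndarray, test_x: np.ndarray, recipe: PrepRecipe,
             n_inner: int) -> Tuple[np.ndarray, np.ndarray]:
    if recipe.pca:
        train_x, test_x, _ = robust_pca_reduce(
            train_x, test_x, recipe.variance_target, n_inner=n_inner)
    if recipe.minmax:
        train_x, test_x, _ = minmax_fit_apply(train_x, test_x)
    return train_x, test_x


@dataclass
class _PreparedFold:
    """One outer fold with all label-independent preparation done."""

    outer_index: int
    test_ids: List[str]
    train_rows: np.ndarray
    test_rows: np.ndarray
    inner: List[tuple]        # (train_rows, val_rows, x_train_prep,
                              #  x_val_prep, x_train_prep_bias, x_val_prep_bias)
    x_train: np.ndarray       # prepared outer-train matrix
    x_test: np.ndarray


def _with_bias(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.hstack([x, np.ones((x.shape[0], 1))]))


def _compile_fold(fold: CVFold, x: np.ndarray, row: Dict[str, int],
                  prep: PrepRecipe) -> _PreparedFold:
    tr = np.array([row[s] for s in fold.train_ids])
    te = np.array([row[s] for s in fold.test_ids])
    inner = []
    for tr_ids, va_ids in fold.inner_folds:
        itr = np.array([row[s] for s in tr_ids])
        iva = np.array([row[s] for s in va_ids])
        xtr, xva = _prepare(x[itr], x[iva], prep, n_inner=len(itr))
        inner.append((itr, iva, xtr, xva, _with_bias(xtr), _with_bias(xva)))
    x_train, x_test = _prepare(x[tr], x[te], prep, n_inner=len(tr))
    return _PreparedFold(fold.outer_index, list(fold.test_ids), tr, te,
                         inner, x_train, x_test)


def _compile_plan(plan: CVPlan, features: pd.DataFrame,
                  prep: PrepRecipe) -> Tuple[List[_PreparedFold], Dict[str, int]]:
    x = np.ascontiguousarray(features.to_numpy(dtype=np.float64))
    row = {sid: i for i, sid in enumerate(features.index)}
    missing = [s for f in plan.folds for s in f.train_ids + f.test_ids
               if s not in row]
    if missing:
        raise ValueError(f"plan subjects missing from features, "
                         f"e.g. {sorted(set(missing))[:3]}")
    return [_compile_fold(f, x, row, prep) for f in plan.folds], row


def _run_fold(spec: ClassifierSpec, cf: _PreparedFold, y_pos: np.ndarray,
              grid: List[Dict[str, float]]):
    """Inner-cycle tuning, refit and outer-test prediction on one fold.

    Returns (test predict_pos, decision values, params, train BAC).
    """
    y_train = y_pos[cf.train_rows]
    if y_train.all() or not y_train.any():
        raise ValueError("single-class outer training set")
    if len(grid) > 1:
        mean_bac = np.zeros(len(grid))
        svm_path = (spec.kind == "linear_svm"
                    and all(list(g) == ["C"] for g in grid))
        cs = (np.array([g["C"] for g in grid], dtype=np.float64)
              if svm_path else None)
        if svm_path and np.any(np.diff(cs) <= 0):
            svm_path = False  # warm starts need an ascending C grid
        for itr, iva, xtr, xva, xtr_b, xva_b in cf.inner:
            ytr, yva = y_pos[itr], y_pos[iva]
            if svm_path:
                # grid search only ranks C values by inner BAC, so the
                # path solve runs at a looser tolerance than the refit
                wmat = svm_dual_cd_path(xtr_b, np.where(ytr, 1.0, -1.0), cs,
                                        100, 1e-3)
                pred_pos = (xva_b @ wmat.T) > 0.0
                for gi in range(len(grid)):
                    mean_bac[gi] += _bac_bool(yva, pred_pos[:, gi])
                continue
            for gi, params in enumerate(grid):
                model = _fit_one(spec.kind, params, xtr, ytr,
                                 spec.decision_threshold)
                mean_bac[gi] += _bac_bool(yva, model.predict_pos(xva))
        top = mean_bac.max()
        tied = [gi for gi in range(len(grid)) if mean_bac[gi] >= top - 1e-12]
        params = grid[min(tied, key=lambda gi: _tie_break_key(grid[gi]))]
    else:
        params = grid[0]
    model = _fit_one(spec.kind, params, cf.x_train, y_train,
                     spec.decision_threshold)
    train_bac = _bac_bool(y_train, model.predict_pos(cf.x_train))
    return (model.predict_pos(cf.x_test), model.decision_values(cf.x_test),
            params, train_bac)


@dataclass
class NestedCVResult:
    """Complete out-of-fold prediction set for one plan."""

    predictions: List[FoldPrediction]
    train_bacs: List[float] = field(default_factory=list)

    @property
    def bac(self) -> float:
        y = np.array([p.true_label for p in self.predictions])
        yhat = np.array([p.predicted_label for p in self.predictions])
        return balanced_accuracy(y, yhat)

    @property
    def mean_train_bac(self) -> float:
        return float(np.mean(self.train_bacs)) if self.train_bacs else float("nan")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "subject_id": p.subject_id, "fold": p.outer_index,
            "true": p.true_label, "predicted": p.predicted_label,
            "decision_value": p.decision_value,
        } for p in self.predictions])


def _selection_view(features: pd.DataFrame, labels: pd.Series, fold: CVFold,
                    prep: PrepRecipe) -> pd.DataFrame:
    selected = greedy_forward_select(
        features.loc[fold.train_ids], labels.loc[fold.train_ids],
        fold.inner_folds, prep.retain_fraction)
    return features[selected]


def fit_predict_fold(spec: ClassifierSpec, fold: CVFold,
                     features: pd.DataFrame, labels: pd.Series,
                     prep: PrepRecipe = PrepRecipe(),
                     ) -> Tuple[List[FoldPrediction], float]:
    """Run one outer fold: inner-cycle tuning, refit, outer-test prediction.

    Returns the fold's out-of-fold predictions and the outer-train
    (resubstitution) balanced accuracy — the raw material of the
    overfitting diagnostic. ``features`` and ``labels`` are indexed by
    subject_id; only rows named by the fold are touched.
    """
    work = features
    if prep.forward_selection:
        work = _selection_view(features, labels, fold, prep)
    x = np.ascontiguousarray(work.to_numpy(dtype=np.float64))
    row = {sid: i for i, sid in enumerate(work.index)}
    cf = _compile_fold(fold, x, row, prep)
    y_pos = (labels.loc[work.index].to_numpy() == "T")
    pred_pos, dv, params, train_bac = _run_fold(spec, cf, y_pos,
                                                _grid_of(spec))
    preds = [FoldPrediction(
        subject_id=sid, true_label="T" if y_pos[row[sid]] else "NT",
        predicted_label="T" if pred_pos[i] else "NT",
        decision_value=float(dv[i]), chosen_hyperparameters=dict(params),
        outer_index=fold.outer_index) for i, sid in enumerate(cf.test_ids)]
    return preds, train_bac


def run_nested_cv(spec: ClassifierSpec, plan: CVPlan, features: pd.DataFrame,
                  labels: pd.Series, prep: PrepRecipe = PrepRecipe(),
                  ) -> NestedCVResult:
    """Run every outer fold of the plan; exactly one prediction per subject."""
    if prep.forward_selection:
        all_preds: List[FoldPrediction] = []
        train_bacs: List[float] = []
        for fold in plan.folds:
            preds, tb = fit_predict_fold(spec, fold, features, labels, prep)
            all_preds.extend(preds)
            train_bacs.append(tb)
        return NestedCVResult(all_preds, train_bacs)
    cfolds, row = _compile_plan(plan, features, prep)
    y_pos = (labels.loc[features.index].to_numpy() == "T")
    grid = _grid_of(spec)
    all_preds = []
    train_bacs = []
    for cf in cfolds:
        pred_pos, dv, params, tb = _run_fold(spec, cf, y_pos, grid)
        train_bacs.append(tb)
        for i, sid in enumerate(cf.test_ids):
            all_preds.append(FoldPrediction(
                subject_id=sid, true_label="T" if y_pos[row[sid]] else "NT",
                predicted_label="T" if pred_pos[i] else "NT",
                decision_value=float(dv[i]),
                chosen_hyperparameters=dict(params),
                outer_index=cf.outer_index))
    return NestedCVResult(all_preds, train_bacs)


def nested_cv_bac_runner(spec: ClassifierSpec, plan: CVPlan,
                         features: pd.DataFrame, prep: PrepRecipe):
    """Compile the plan once and return ``labels_array -> outer BAC``.

    The returned callable takes a boolean is-T array aligned with
    ``features.index``. Used by the permutation test, where only the
    labels change between runs. Falls back to the full per-run path when
    forward selection is on (selection is label-dependent).
    """
    if prep.forward_selection:
        idx = features.index

        def slow_runner(y_pos: np.ndarray) -> float:
            lab = pd.Series(np.where(y_pos, "T", "NT"), index=idx)
            return run_nested_cv(spec, plan, features, lab, prep).bac
        return slow_runner

    cfolds, _ = _compile_plan(plan, features, prep)
    grid = _grid_of(spec)
    test_rows = np.concatenate([cf.test_rows for cf in cfolds])

    def runner(y_pos: np.ndarray) -> float:
        preds = []
        for cf in cfolds:
            pred_pos, _, _, _ = _run_fold(spec, cf, y_pos, grid)
            preds.append(pred_pos)
        return _bac_bool(y_pos[test_rows], np.concatenate(preds))
    return runner


# ---------------------------------------------------------------------------
# simple (non-nested) LPO logistic path for single-score features


def _batched_newton_1d(xtr: np.ndarray, ytr: np.ndarray,
                       max_iter: int = 25) -> Tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson for F simultaneous single-feature logistic fits.

    ``xtr``/``ytr`` are (F, n_train). Returns intercepts and slopes (F,).
    A small ridge keeps separable folds finite; the iteration cap keeps
    their predictions at the maximum-likelihood limit.
    """
    f = xtr.shape[0]
    b0 = np.zeros(f)
    b1 = np.zeros(f)
    ridge = 1e-8
    for _ in range(max_iter):
        eta = np.clip(b0[:, None] + b1[:, None] * xtr, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        r = ytr - p
        w = p * (1.0 - p)
        g0 = r.sum(axis=1)
        g1 = (r * xtr).sum(axis=1)
        h00 = w.sum(axis=1) + ridge
        h01 = (w * xtr).sum(axis=1)
        h11 = (w * xtr * xtr).sum(axis=1) + ridge
        det = h00 * h11 - h01 * h01
        s0 = (h11 * g0 - h01 * g1) / det
        s1 = (h00 * g1 - h01 * g0) / det
        b0 += s0
        b1 += s1
        if max(np.abs(s0).max(), np.abs(s1).max()) < 1e-8:
            break
    return b0, b1


def simple_lpo_bac(x: np.ndarray, y_pos: np.ndarray, train_idx: np.ndarray,
                   test_idx: np.ndarray) -> float:
    """Out-of-fold BAC of the single-feature logistic path, batched over
    folds. ``train_idx`` (F, n_train) and ``test_idx`` (F, n_test) index
    into ``x``/``y_pos``; fold sizes must be uniform (always true for LPO).
    """
    xtr = x[train_idx]
    ytr = y_pos[train_idx].astype(np.float64)
    b0, b1 = _batched_newton_1d(xtr, ytr)
    eta = b0[:, None] + b1[:, None] * x[test_idx]
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    pred_pos = (prob > 0.5).ravel()
    return _bac_bool(y_pos[test_idx].ravel(), pred_pos)


def lpo_pair_indices(y_pos: np.ndarray, rng: np.random.Generator,
                     strata: np.ndarray = None,
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Row-index arrays of a leave-one-pair-out design derived from the
    labels themselves: one T paired with one NT (within a stratum when
    ``strata`` is given), train = everyone else. Used to re-derive the
    fold assignment for permuted labels so the permutation null keeps the
    matched, group-balanced design of the observed run.
    """
    n = len(y_pos)
    groups = [np.zeros(n, dtype=bool) | True] if strata is None else [
        strata == s for s in np.unique(strata)]
    pairs = []
    for g in groups:
        t = np.flatnonzero(y_pos & g)
        nt = np.flatnonzero(~y_pos & g)
        if len(t) != len(nt):
            raise ValueError("pairing requires per-stratum group parity")
        t = rng.permutation(t)
        nt = rng.permutation(nt)
        pairs.extend(zip(t, nt))
    test_idx = np.array(pairs)
    all_idx = np.arange(n)
    train_idx = np.array([np.delete(all_idx, pair) for pair in pairs])
    return train_idx, test_idx


def plan_index_arrays(plan: CVPlan, index: pd.Index) -> Tuple[np.ndarray, np.ndarray]:
    """(train_idx, test_idx) row-index matrices for a uniform-fold plan."""
    row = {sid: i for i, sid in enumerate(index)}
    sizes = {len(f.train_ids) for f in plan.folds}
    if len(sizes) != 1:
        raise ValueError("plan folds have non-uniform training sizes")
    train_idx = np.array([[row[s] for s in f.train_ids] for f in plan.folds])
    test_idx = np.array([[row[s] for s in f.test_ids] for f in plan.folds])
    return train_idx, test_idx


def fit_simple_lpo_logistic(score: pd.Series, labels: pd.Series,
                            plan: CVPlan, threshold: float = 0.5,
                            ) -> NestedCVResult:
    """Single-feature logistic regression in a simple (non-nested) LPO CV.

    Used for the composite scores (PRS, ERS): no hyperparameters, so no
    inner cycle — fit on the outer-train rows, threshold the predicted
    probability at 0.5 on the outer-test pair.
    """
    if isinstance(score, pd.DataFrame):
        if score.shape[1] != 1:
            raise ValueError("simple logistic path takes exactly one feature")
        score = score.iloc[:, 0]
    x_all = score.to_numpy(dtype=np.float64)
    ids = list(score.index)
    row = {sid: i for i, sid in enumerate(ids)}
    y_pos = (labels.loc[ids].to_numpy() == "T")
    preds: List[FoldPrediction] = []
    train_bacs: List[float] = []
    for fold in plan.folds:
        tr = np.array([row[s] for s in fold.train_ids])
        te = np.array([row[s] for s in fold.test_ids])
        b0, b1 = _batched_newton_1d(x_all[tr][None, :],
                                    y_pos[tr].astype(np.float64)[None, :])
        model = _LinearModel(np.array([b1[0], b0[0]]), probabilistic=True,
                             threshold=threshold)
        x_te = x_all[te].reshape(-1, 1)
        dv = model.decision_values(x_te)
        pred_pos = model.predict_pos(x_te)
        train_bacs.append(_bac_bool(
            y_pos[tr], model.predict_pos(x_all[tr].reshape(-1, 1))))
        for i, sid in enumerate(fold.test_ids):
            preds.append(FoldPrediction(
                subject_id=sid, true_label="T" if y_pos[row[sid]] else "NT",
                predicted_label="T" if pred_pos[i] else "NT",
                decision_value=float(dv[i]), chosen_hyperparameters={},
                outer_index=fold.outer_index))
    return NestedCVResult(preds, train_bacs)
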