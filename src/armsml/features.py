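"""Per-fold feature preparation.

All preparation is fit on training rows only and applied to held-out rows
with the training parameters — the module's interfaces take explicit
train/test pairs so outer-test information can never leak into the fit.

Steps, by modality family:

* regional volumes (ROIGM/ROIWM): divide by the subject's total
  intracranial volume (TIV), a per-subject normalization;
* everything entering the SVM: per-feature min-max scaling to [0, 1]
  computed on the training rows (held-out values outside the training
  range are deliberately left unclamped);
* voxel-wise families (VBGM/VBWM): robust PCA — median/MAD
  standardization followed by an eigendecomposition of the training
  covariance, retaining the smallest number of components explaining 80 %
  of the variance, capped at half the inner-cycle sample size;
* regional families: greedy forward feature selection driven by mean
  inner-fold balanced accuracy, retaining the 10 % most predictive
  features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._solvers import svm_dual_cd
from .types import ModalityFeatures

__all__ = [
    "scale_to_tiv",
    "minmax_fit_apply",
    "MinMaxScalerModel",
    "robust_pca_reduce",
    "ReductionModel",
    "greedy_forward_select",
]


def scale_to_tiv(features: ModalityFeatures) -> ModalityFeatures:
    """Divide every regional volume by the subject's TIV; consumes the TIV.

    Stateless per-subject normalization, so it is safe to apply once to the
    whole table before cross-validation.
    """
    if features.family not in ("ROIGM", "ROIWM"):
        raise ValueError(f"TIV scaling applies to ROI volume families, "
                         f"not {features.family}")
    if features.tiv is None:
        raise ValueError("TIV already consumed or never provided")
    tiv = features.tiv
    if (tiv <= 0).any() or tiv.isna().any():
        raise ValueError("TIV must be positive for every subject")
    scaled = features.values.div(tiv, axis=0)
    return ModalityFeatures(scaled, features.family, tiv=None)


@dataclass
class MinMaxScalerModel:
    mins: np.ndarray
    ranges: np.ndarray  # zero where the training feature was constant

    def transform(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x, dtype=float)
        nz = self.ranges > 0
        out[:, nz] = (x[:, nz] - self.mins[nz]) / self.ranges[nz]
        return out


def minmax_fit_apply(train: np.ndarray, test: Optional[np.ndarray] = None,
                     ) -> Tuple[np.ndarray, Optional[np.ndarray], MinMaxScalerModel]:
    """Per-feature (x - min)/(max - min) with min/max from train only.

    Held-out values may land outside [0, 1] (not clamped); constant
    training features map to 0 everywhere.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    mins = train.min(axis=0)
    ranges = train.max(axis=0) - mins
    model = MinMaxScalerModel(mins, ranges)
    test_out = model.transform(np.asarray(test, dtype=float)) if test is not None else None
    return model.transform(train), test_out, model


@dataclass
class ReductionModel:
    """Fitted robust-PCA reduction (training medians/MADs and loadings)."""

    centers: np.ndarray
    scales: np.ndarray
    kept_columns: np.ndarray  # boolean mask of non-degenerate features
    components: np.ndarray    # (n_components, n_kept) orthonormal loadings
    explained_variance_ratio: np.ndarray
    n_components: int
    component_cap: int
    variance_target: float

    def transform(self, x: np.ndarray) -> np.ndarray:
        xk = (np.asarray(x, dtype=float)[:, self.kept_columns]
              - self.centers) / self.scales
        return xk @ self.components.T

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
            "component_cap": self.component_cap,
            "variance_target": self.variance_target,
        }


def robust_pca_reduce(train: np.ndarray, test: Optional[np.ndarray],
                      variance_target: float = 0.8,
                      n_inner: Optional[int] = None, robust: bool = True,
                      ) -> Tuple[np.ndarray, Optional[np.ndarray], ReductionModel]:
    """Robust PCA of the training matrix with projection of held-out rows.

    Features are centered by their training median and scaled by their
    training MAD (median absolute deviation; MAD-zero features dropped),
    then eigendecomposed. The smallest k whose cumulative explained
    variance reaches ``variance_target`` is retained, truncated at
    ``floor(n_inner / 2)`` where ``n_inner`` is the inner-cycle training
    size (defaults to the number of training rows). ``robust=False``
    switches to classic mean/SD standardization.
    """
    train = np.asarray(train, dtype=float)
    n = train.shape[0]
    if n < 2:
        raise ValueError("robust PCA needs at least 2 training subjects")
    if n_inner is None:
        n_inner = n
    cap = max(1, n_inner // 2)
    if robust:
        centers = np.median(train, axis=0)
        scales = np.median(np.abs(train - centers), axis=0)
    else:
        centers = train.mean(axis=0)
        scales = train.std(axis=0, ddof=1)
    kept = scales > 0
    if not kept.any():
        raise ValueError("all features degenerate (zero spread)")
    z = (train[:, kept] - centers[kept]) / scales[kept]
    # SVD of the centered-scaled training matrix == eigendecomposition of
    # its covariance, without forming the (p x p) matrix
    zc = z - z.mean(axis=0)
    _, s, vt = np.linalg.svd(zc, full_matrices=False)
    var = s ** 2
    if var.size == 0 or var.sum() <= 0:
        raise ValueError("training matrix has no variance after scaling")
    positive = var > max(1e-12, var[0] * 1e-12)
    var = var[positive]
    vt = vt[positive]
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    k_target = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k_target, cap, len(var))
    model = ReductionModel(
        centers=centers[kept], scales=scales[kept], kept_columns=kept,
        components=vt[:k], explained_variance_ratio=ratio[:k],
        n_components=k, component_cap=cap, variance_target=variance_target)
    test_out = model.transform(test) if test is not None else None
    return model.transform(train), test_out, model


def _svm_bac(x_tr: np.ndarray, y_tr: np.ndarray, x_va: np.ndarray,
             y_va: np.ndarray, C: float = 1.0) -> float:
    """Balanced accuracy of a min-max-scaled linear SVM on one inner fold."""
    tr, va, _ = minmax_fit_apply(x_tr, x_va)
    xb = np.hstack([tr, np.ones((tr.shape[0], 1))])
    w = svm_dual_cd(xb, y_tr, C)
    pred = np.hstack([va, np.ones((va.shape[0], 1))]) @ w > 0
    pos, neg = y_va > 0, y_va < 0
    se = pred[pos].mean() if pos.any() else 0.0
    sp = (~pred[neg]).mean() if neg.any() else 0.0
    return 0.5 * (se + sp)


def greedy_forward_select(train: pd.DataFrame, labels: Sequence[str],
                          inner_folds: Sequence[Tuple[Sequence[str], Sequence[str]]],
                          retain_fraction: float = 0.1,
                          svm_C: float = 1.0) -> List[str]:
    """Greedy forward feature selection on the inner cross-validation cycle.

    Starting from an empty set, each step adds the candidate feature that
    maximizes the mean inner-fold balanced accuracy of a linear SVM fit on
    the already-selected features plus the candidate, stopping once
    ``max(1, floor(retain_fraction * p))`` features are selected. Ties are
    broken toward the lowest feature index. Only the outer-train rows are
    ever passed in, so outer-test labels cannot influence the selection.

    ``train`` is indexed by subject_id; ``inner_folds`` holds
    (train_ids, validation_ids) pairs over those subjects.
    """
    p = train.shape[1]
    if p == 0:
        raise ValueError("no candidate features")
    target = max(1, int(retain_fraction * p))
    lab = pd.Series(np.where(np.asarray(labels) == "T", 1.0, -1.0),
                    index=train.index)
    fold_data = []
    for tr_ids, va_ids in inner_folds:
        y_tr = lab.loc[list(tr_ids)].to_numpy()
        y_va = lab.loc[list(va_ids)].to_numpy()
        if len(np.unique(y_tr)) < 2:
            raise ValueError("an inner training fold has a single class")
        fold_data.append((train.loc[list(tr_ids)].to_numpy(),
                          y_tr,
                          train.loc[list(va_ids)].to_numpy(),
                          y_va))
    selected: List[int] = []
    remaining = list(range(p))
    while len(selected) < target:
        best_j, best_bac = None, -1.0
        for j in remaining:
            cols = selected + [j]
            bac = float(np.mean([
                _svm_bac(xtr[:, cols], ytr, xva[:, cols], yva, svm_C)
                for xtr, ytr, xva, yva in fold_data]))
            if bac > best_bac + 1e-12:
                best_j, best_bac = j, bac
        selected.append(best_j)
        remaining.remove(best_j)
    return [train.columns[j] for j in selected]
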