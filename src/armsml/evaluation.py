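"""Performance measures, permutation testing and replicate aggregation.

The unit of evidence is one balanced bootstrap replicate: a nested CV run
produces one out-of-fold confusion matrix, summarized as sensitivity (SE),
specificity (SP), balanced accuracy (BAC = (SE+SP)/2), positive/negative
likelihood ratios and the diagnostic odds ratio. Whether a replicate's BAC
beats chance (50 %) is judged by a label-permutation test that re-runs the
entire nested CV — preparation, tuning and all — on the same fold
structure for every permutation, so training-phase optimism is part of the
null. A feature/configuration combination counts as predictive only when
at least 3 of its 5 replicates are individually significant (more
generally, at least 60 %); modalities passing that gate would be admitted
to a multimodal model, and with no modality passing, no multimodal model
is trained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import models
from .models import PrepRecipe
from .types import (BootstrapReport, ClassifierSpec, CVPlan, FoldPrediction,
                    PerformanceReport, TestResult)

__all__ = [
    "confusion_metrics",
    "permutation_test_bac",
    "PermutationResult",
    "aggregate_bootstraps",
    "wilcoxon_median_bac",
    "multimodal_gate",
    "overfitting_report",
    "summarize_replicates",
]


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.inf if num > 0 else math.nan
    return num / den


def confusion_metrics(predictions: Sequence[FoldPrediction]) -> PerformanceReport:
    """Confusion-matrix measures with T as the positive class.

    Undefined ratios (SP = 1 or SP = 0, SE = 1) are reported as explicit
    infinities / NaN rather than silently finite numbers.
    """
    y = np.array([p.true_label for p in predictions])
    yhat = np.array([p.predicted_label for p in predictions])
    if len(set(y)) < 2:
        raise ValueError("need both classes in the truth vector")
    tp = int(((y == "T") & (yhat == "T")).sum())
    fn = int(((y == "T") & (yhat == "NT")).sum())
    tn = int(((y == "NT") & (yhat == "NT")).sum())
    fp = int(((y == "NT") & (yhat == "T")).sum())
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    plr = _ratio(se, 1.0 - sp)
    nlr = _ratio(1.0 - se, sp)
    if math.isnan(plr) or math.isnan(nlr):
        dor = math.nan
    elif math.isinf(plr) or nlr == 0.0:
        dor = math.inf
    elif math.isinf(nlr):
        dor = 0.0
    else:
        dor = plr / nlr
    return PerformanceReport(TP=tp, FN=fn, TN=tn, FP=fp, SE=se, SP=sp,
                             BAC=0.5 * (se + sp), PLR=plr, NLR=nlr, DOR=dor)


@dataclass
class PermutationResult:
    observed_bac: float
    null_bacs: np.ndarray
    p_value: float


def _permute_within_strata(y: np.ndarray, strata, rng) -> np.ndarray:
    if strata is None:
        return rng.permutation(y)
    out = y.copy()
    for s in np.unique(strata):
        mask = strata == s
        out[mask] = rng.permutation(y[mask])
    return out


def permutation_test_bac(spec: ClassifierSpec, plan: CVPlan,
                         features: pd.DataFrame, labels: pd.Series,
                         n_permutations: int = 1000, seed: int = 0,
                         prep: PrepRecipe = PrepRecipe(),
                         simple_logistic: bool = False,
                         plan_builder=None, strata: pd.Series = None,
                         ) -> PermutationResult:
    """Permutation test of the out-of-fold BAC against the 50 % chance level.

    Labels are permuted uniformly at random over the whole subsample
    (within scan-protocol strata when ``strata`` is given, preserving the
    matched design's per-protocol group counts), and the full pipeline is
    re-run per permutation. The fold assignment is re-derived from the
    permuted labels with the same scheme and seed — the observed run's
    folds are label-aligned (balanced train sets, one-per-group test
    pairs), so freezing them under permutation would depress the null BAC
    and inflate the type-I rate. ``plan_builder`` (labels -> CVPlan)
    supplies that re-derivation for nested plans; the single-score
    logistic path (``simple_logistic=True``) re-pairs internally. With
    ``plan_builder=None`` the nested path falls back to the frozen
    observed plan.

    p = (1 + #{BAC_perm >= BAC_obs}) / (1 + B), the add-one estimator, so
    p is never exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    strata_arr = None if strata is None else np.asarray(
        strata.loc[features.index if not simple_logistic else
                   (features.iloc[:, 0] if isinstance(features, pd.DataFrame)
                    else features).index])

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)

    if simple_logistic:
        score = (features.iloc[:, 0] if isinstance(features, pd.DataFrame)
                 else features)
        x = score.to_numpy(dtype=np.float64)
        y_pos0 = (labels.loc[score.index].to_numpy() == "T")
        tr0, te0 = models.plan_index_arrays(plan, score.index)
        observed = models.simple_lpo_bac(x, y_pos0, tr0, te0)
        for b in range(n_permutations):
            y_perm = _permute_within_strata(y_pos0, strata_arr, rng)
            tr, te = models.lpo_pair_indices(y_perm, rng, strata_arr)
            null[b] = models.simple_lpo_bac(x, y_perm, tr, te)
    else:
        y_pos0 = (labels.loc[features.index].to_numpy() == "T")
        runner = models.nested_cv_bac_runner(spec, plan, features, prep)
        observed = runner(y_pos0)
        if plan_builder is None:
            for b in range(n_permutations):
                null[b] = runner(_permute_within_strata(y_pos0, strata_arr, rng))
        else:
            idx = features.index
            for b in range(n_permutations):
                y_perm = _permute_within_strata(y_pos0, strata_arr, rng)
                lab = pd.Series(np.where(y_perm, "T", "NT"), index=idx)
                plan_b = plan_builder(lab)
                null[b] = models.run_nested_cv(spec, plan_b, features, lab,
                                               prep).bac
    p = (1.0 + float((null >= observed - 1e-12).sum())) / (1.0 + n_permutations)
    return PermutationResult(observed, null, p)


def aggregate_bootstraps(p_values: Sequence[float], alpha: float = 0.05,
                         min_significant_fraction: float = 0.6,
                         ) -> tuple:
    """(decision, count): significant replicates are those with p < alpha;
    the decision is true iff count >= ceil(fraction * n) — with five
    replicates and the default 60 % fraction, at least 3 of 5."""
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    count = int(sum(p < alpha for p in p_values))
    threshold = math.ceil(min_significant_fraction * len(p_values))
    return count >= threshold, count


def wilcoxon_median_bac(bacs: Sequence[float], chance: float = 0.5) -> TestResult:
    """One-tailed Wilcoxon signed-rank test that the median replicate BAC
    exceeds chance, exact by enumeration of all 2^n sign assignments.

    Differences exactly at chance are dropped; midranks handle ties in the
    absolute differences. Requires n <= 20 after dropping (the enumeration
    is exhaustive).
    """
    d = np.asarray(bacs, dtype=float) - chance
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon_signed_rank", "one_sided_greater")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    count = 0
    for signs in product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if w >= w_obs - 1e-12:
            count += 1
    return TestResult(w_obs, count / 2 ** n, "wilcoxon_signed_rank",
                      "one_sided_greater")


def multimodal_gate(reports: Sequence[BootstrapReport]) -> List[str]:
    """Modalities whose aggregate decision is true; an empty result means
    no multimodal model is trained."""
    if not reports:
        raise ValueError("at least one modality report required")
    admitted = sorted({r.modality for r in reports if r.decision})
    return admitted


def overfitting_report(train_bacs: Sequence[float], test_bacs: Sequence[float],
                       n_boot: int = 2000, seed: int = 0) -> dict:
    """Mean train-minus-test BAC gap with a bootstrap 95 % CI — the
    resubstitution-optimism diagnostic."""
    train_bacs = np.asarray(train_bacs, dtype=float)
    test_bacs = np.asarray(test_bacs, dtype=float)
    if train_bacs.shape != test_bacs.shape:
        raise ValueError("train and test BAC sequences must be paired")
    gaps = train_bacs - test_bacs
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(gaps), size=(n_boot, len(gaps)))
    boot_means = gaps[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return {"mean_gap": float(gaps.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "n": len(gaps)}


def _fmt(values: Sequence[float], scale: float = 1.0) -> str:
    v = np.asarray(values, dtype=float) * scale
    finite = v[np.isfinite(v)]
    if len(finite) == 0:
        return "inf"
    return (f"{finite.mean():.1f} ± {finite.std(ddof=1) if len(finite) > 1 else 0.0:.1f} "
            f"[{finite.min():.1f}, {finite.max():.1f}]")


def summarize_replicates(reports: Sequence[PerformanceReport],
                         p_values: Sequence[float],
                         alpha: float = 0.05) -> pd.DataFrame:
    """One summary row per metric in the published table layout:
    mean ± SD [min, max] across replicates, plus the significant-model
    count."""
    rows = {
        "SE (%)": _fmt([r.SE for r in reports], 100.0),
        "SP (%)": _fmt([r.SP for r in reports], 100.0),
        "BAC (%)": _fmt([r.BAC for r in reports], 100.0),
        "PLR": _fmt([r.PLR for r in reports]),
        "NLR": _fmt([r.NLR for r in reports]),
        "DOR": _fmt([r.DOR for r in reports]),
        "Significant models": str(int(sum(p < alpha for p in p_values))),
    }
    return pd.DataFrame({"value": rows})
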