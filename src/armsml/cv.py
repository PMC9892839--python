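"""Nested cross-validation plans and hyperparameter grids.

Three outer schemes are supported, all with stratified inner folds for
hyperparameter tuning:

LSO
    leave-one-scan-acquisition-protocol-out: one outer fold per protocol,
    the whole protocol held out — the hardest test of scanner
    generalization.
LPO
    leave-one-per-group-out: each outer fold holds out one T and one NT
    subject from the same protocol, so the test pair shares a site and the
    train set keeps its T/NT-per-protocol proportions.
KFOLD
    classic stratified k-fold (k=5 by default) by group.
"""

from __future__ import annotations

from collections import defaultdict
from typing import List

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .types import BalancedSubsample, CohortTable, CVFold, CVPlan, HyperparameterGrid

__all__ = [
    "build_lso_plan",
    "build_lpo_plan",
    "build_kfold_plan",
    "default_grids",
]


def default_grids() -> HyperparameterGrid:
    """The classifier search grids: C = 2^l for l in -5..4 (10 values);
    elastic-net l1 ratio 0:0.1:1 (11 values) and lambda 0.01:0.01:1
    (100 values)."""
    return HyperparameterGrid(
        svm_C=tuple(2.0 ** l for l in range(-5, 5)),
        enet_l1=tuple(round(0.1 * i, 1) for i in range(11)),
        enet_lambda=tuple(round(0.01 * i, 2) for i in range(1, 101)),
    )


def _labels_for(cohort: CohortTable, ids: List[str],
                override=None) -> np.ndarray:
    if override is not None:
        return override.loc[ids].to_numpy()
    ph = cohort.phenotypes.set_index("subject_id")
    return ph.loc[ids, "transition"].to_numpy()


def _inner_stratified(ids: List[str], labels: np.ndarray, inner_k: int,
                      rng_seed: int) -> List[tuple]:
    ids = np.asarray(ids)
    counts = np.bincount((labels == "T").astype(int), minlength=2)
    k = min(inner_k, int(counts.min()))
    if k < 2:
        # too few subjects per class to split: no inner cycle, the
        # hyperparameter search falls back to its deterministic tie-break
        return []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return [(list(ids[tr]), list(ids[va]))
            for tr, va in skf.split(ids, labels)]


def build_lso_plan(subsample: BalancedSubsample, cohort: CohortTable,
                   inner_k: int = 5, seed: int = 0,
                   labels=None) -> CVPlan:
    """One outer fold per scan protocol; inner stratified k-fold on the
    remaining protocols' subjects. ``labels`` optionally overrides the
    cohort's transition labels (used when re-deriving folds for permuted
    labels)."""
    ids = subsample.subject_ids
    ph = cohort.phenotypes.set_index("subject_id")
    protocols = ph.loc[ids, "protocol"]
    unique = sorted(protocols.unique())
    if len(unique) < 2:
        raise ValueError("LSO requires at least 2 protocols")
    folds = []
    for i, proto in enumerate(unique):
        test_ids = [s for s in ids if protocols[s] == proto]
        train_ids = [s for s in ids if protocols[s] != proto]
        inner = _inner_stratified(train_ids,
                                  _labels_for(cohort, train_ids, labels),
                                  inner_k, seed + i)
        folds.append(CVFold(i, train_ids, test_ids, inner))
    return CVPlan("LSO", folds, seed)


def build_lpo_plan(subsample: BalancedSubsample, cohort: CohortTable,
                   inner_k: int = 5, seed: int = 0,
                   by_protocol: bool = True, labels=None) -> CVPlan:
    """Outer folds pair one T with one NT subject, from the same protocol
    when ``by_protocol`` (the imaging variant; non-imaging modalities pair
    freely); every subject is tested exactly once."""
    ph = cohort.phenotypes.set_index("subject_id")
    rng = np.random.default_rng(seed)
    by_proto_t = defaultdict(list)
    by_proto_nt = defaultdict(list)
    for sid in subsample.subject_ids_T:
        key = ph.loc[sid, "protocol"] if by_protocol else "all"
        by_proto_t[key].append(sid)
    for sid in subsample.subject_ids_NT:
        key = ph.loc[sid, "protocol"] if by_protocol else "all"
        by_proto_nt[key].append(sid)
    if set(by_proto_t) != set(by_proto_nt) or any(
            len(by_proto_t[p]) != len(by_proto_nt[p]) for p in by_proto_t):
        raise ValueError("LPO requires per-protocol T/NT parity")
    pairs = []
    for proto in sorted(by_proto_t):
        ts = list(by_proto_t[proto])
        nts = list(by_proto_nt[proto])
        rng.shuffle(ts)
        rng.shuffle(nts)
        pairs.extend(zip(ts, nts))
    all_ids = subsample.subject_ids
    folds = []
    for i, (t_id, nt_id) in enumerate(pairs):
        test_ids = [t_id, nt_id]
        train_ids = [s for s in all_ids if s not in test_ids]
        inner = _inner_stratified(train_ids,
                                  _labels_for(cohort, train_ids, labels),
                                  inner_k, seed + i)
        folds.append(CVFold(i, train_ids, test_ids, inner))
    return CVPlan("LPO", folds, seed)


def build_kfold_plan(subsample: BalancedSubsample, cohort: CohortTable,
                     k: int = 5, inner_k: int = 5, seed: int = 0,
                     labels=None) -> CVPlan:
    """Stratified-by-group outer k-fold with stratified inner folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.asarray(subsample.subject_ids)
    labels = _labels_for(cohort, list(ids), labels)
    counts = np.bincount((labels == "T").astype(int))
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) smaller than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (tr, te) in enumerate(skf.split(ids, labels)):
        train_ids, test_ids = list(ids[tr]), list(ids[te])
        inner = _inner_stratified(train_ids, labels[tr], inner_k, seed + i)
        folds.append(CVFold(i, train_ids, test_ids, inner))
    return CVPlan("KFOLD", folds, seed)
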