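"""Shared domain containers for the ARMS transition-prediction pipeline.

Everything tabular is a :class:`pandas.DataFrame`; the dataclasses here are
thin, typed envelopes that carry the metadata the pipeline needs to route a
table through the right preparation steps (modality family, TIV column,
fold membership, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Modality families understood by the feature-preparation stage.
FAMILIES = (
    "ROIGM", "ROIWM", "ROISurface", "VBGM", "VBWM",
    "SNP", "EQTL", "ENV", "SCORE",
)

#: Regional sMRI families eligible for greedy forward feature selection.
ROI_FAMILIES = ("ROIGM", "ROIWM", "ROISurface")

#: Voxel-wise sMRI families eligible for robust-PCA reduction.
VOXEL_FAMILIES = ("VBGM", "VBWM")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group comparison statistic."""

    statistic: float
    p_value: float
    test_name: str
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass
class CohortTable:
    """Subject roster with demographics, scan protocol and transition label.

    ``phenotypes`` columns: subject_id, age_years, sex (male/female),
    protocol (P1/P2/P3), transition (T/NT), followup_years.
    """

    phenotypes: pd.DataFrame
    modality_membership: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.phenotypes["subject_id"]
        if ids.duplicated().any():
            raise ValueError("duplicate subject_ids in cohort")
        known = set(ids)
        for sid in self.modality_membership:
            if sid not in known:
                raise ValueError(f"modality membership for unknown subject {sid!r}")

    @property
    def subject_ids(self) -> list:
        return list(self.phenotypes["subject_id"])

    def ids_of(self, transition: str) -> list:
        ph = self.phenotypes
        return list(ph.loc[ph["transition"] == transition, "subject_id"])

    def subset(self, subject_ids: Sequence[str]) -> "CohortTable":
        keep = set(subject_ids)
        ph = self.phenotypes[self.phenotypes["subject_id"].isin(keep)].reset_index(drop=True)
        mm = {k: v for k, v in self.modality_membership.items() if k in keep}
        return CohortTable(ph, mm)

    def __len__(self) -> int:
        return len(self.phenotypes)


@dataclass(frozen=True)
class EffectSpec:
    """Simulation control: how much group signal the generator injects.

    ``cohens_d = 0`` is the null regime; informative features have their
    T/NT group means separated by ``cohens_d`` within-group SDs.
    """

    n_informative: int = 0
    cohens_d: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 0:
            raise ValueError("n_informative must be >= 0")


@dataclass
class ModalityFeatures:
    """Subjects x features table tagged with its modality family.

    ``values`` is indexed by subject_id. ``tiv`` (total intracranial volume,
    mm^3) is carried separately for regional volume families until consumed
    by TIV scaling.
    """

    values: pd.DataFrame
    family: str
    tiv: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.tiv is not None and not self.tiv.index.equals(self.values.index):
            raise ValueError("tiv index does not match feature table index")

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def loc(self, subject_ids: Sequence[str]) -> "ModalityFeatures":
        tiv = self.tiv.loc[list(subject_ids)] if self.tiv is not None else None
        return ModalityFeatures(self.values.loc[list(subject_ids)], self.family, tiv)


@dataclass(frozen=True)
class MatchCriteria:
    """Demographic matching thresholds for balanced subsampling."""

    age_p_threshold: float = 0.05
    sex_p_threshold: float = 0.05
    protocol_one_to_one: bool = True
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        for p in (self.age_p_threshold, self.sex_p_threshold):
            if not (0.0 < p < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass
class BalancedSubsample:
    """A group-balanced, demographically matched draw of the cohort."""

    subject_ids_T: list
    subject_ids_NT: list
    attempt_count: int
    age_p: float
    sex_p: float
    seed: int

    @property
    def subject_ids(self) -> list:
        return list(self.subject_ids_T) + list(self.subject_ids_NT)

    def __post_init__(self) -> None:
        if len(self.subject_ids_T) != len(self.subject_ids_NT):
            raise ValueError("balanced subsample requires |T| == |NT|")


@dataclass
class CVFold:
    """One outer fold of a nested cross-validation plan."""

    outer_index: int
    train_ids: list
    test_ids: list
    inner_folds: list  # list of (train_ids, validation_ids)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("outer train/test overlap")
        outer_train = set(self.train_ids)
        for tr, va in self.inner_folds:
            if not set(tr) <= outer_train or not set(va) <= outer_train:
                raise ValueError("inner folds must partition the outer-train set only")
            if set(tr) & set(va):
                raise ValueError("inner train/validation overlap")


@dataclass
class CVPlan:
    """Sequence of outer folds under one scheme (LSO, LPO or KFOLD)."""

    scheme: str
    folds: list
    seed: int

    def __post_init__(self) -> None:
        if self.scheme not in ("LSO", "LPO", "KFOLD"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        seen: set = set()
        for f in self.folds:
            if seen & set(f.test_ids):
                raise ValueError("subject appears in more than one outer test set")
            seen.update(f.test_ids)

    @property
    def all_test_ids(self) -> set:
        return {sid for f in self.folds for sid in f.test_ids}


@dataclass(frozen=True)
class HyperparameterGrid:
    """The classifier search grids (SVM C; elastic-net l1 ratio and lambda)."""

    svm_C: tuple
    enet_l1: tuple
    enet_lambda: tuple


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier family to run and over which grid."""

    kind: str  # linear_svm | logistic | elastic_net
    svm_C: tuple = ()
    enet_l1: tuple = ()
    enet_lambda: tuple = ()
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("linear_svm", "logistic", "elastic_net"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class FoldPrediction:
    """Out-of-fold prediction for one subject."""

    subject_id: str
    true_label: str
    predicted_label: str
    decision_value: float
    chosen_hyperparameters: dict
    outer_index: int


@dataclass
class PerformanceReport:
    """Confusion-matrix performance measures (ARMS-T is the positive class)."""

    TP: int
    FN: int
    TN: int
    FP: int
    SE: float
    SP: float
    BAC: float
    PLR: float  # may be math.inf when SP == 1
    NLR: float
    DOR: float  # may be math.inf / nan when a ratio is undefined


@dataclass
class BootstrapReport:
    """Per-replicate performance plus the aggregate significance decision."""

    modality: str
    configuration: str
    reports: list  # PerformanceReport per replicate
    permutation_p_values: list
    train_bacs: list
    n_significant: int
    decision: bool


def as_float_matrix(df: pd.DataFrame) -> np.ndarray:
    return np.ascontiguousarray(df.to_numpy(dtype=np.float64))
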