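"""Delimited-text interfaces: every table crosses the package boundary as
UTF-8 TSV with a header row, NA for missing."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import pandas as pd

from .types import BalancedSubsample, CohortTable, CVPlan, ModalityFeatures

__all__ = [
    "write_phenotypes", "read_phenotypes",
    "write_features", "read_features",
    "write_dosages", "read_dosages",
    "write_weights", "read_weights",
    "write_exposures", "read_exposures",
    "write_subsample_manifest", "write_cv_plan_json",
    "write_scores", "write_predictions",
]

_PHENO_COLS = ["subject_id", "age_years", "sex", "protocol", "transition",
               "followup_years"]


def _write(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def _read(path, **kw) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], **kw)
    return df


def write_phenotypes(cohort: CohortTable, path) -> None:
    _write(cohort.phenotypes[_PHENO_COLS], path)


def read_phenotypes(path) -> CohortTable:
    df = _read(path)
    missing = set(_PHENO_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype TSV lacks columns: {sorted(missing)}")
    membership = {sid: frozenset({"smri", "genetic", "environmental"})
                  for sid in df["subject_id"]}
    return CohortTable(df[_PHENO_COLS].copy(), membership)


def write_features(features: ModalityFeatures, path) -> None:
    df = features.values.copy()
    if features.tiv is not None:
        df["tiv"] = features.tiv
    _write(df.reset_index(), path)


def read_features(path, family: str) -> ModalityFeatures:
    df = _read(path).set_index("subject_id")
    tiv = None
    if "tiv" in df.columns:
        tiv = df.pop("tiv")
    return ModalityFeatures(df, family, tiv)


def write_dosages(dosages: ModalityFeatures, path) -> None:
    _write(dosages.values.reset_index(), path)


def read_dosages(path) -> pd.DataFrame:
    df = _read(path).set_index("subject_id")
    bad = ~df.isin([0, 1, 2]) & df.notna()
    if bad.any().any():
        raise ValueError("dosage TSV contains values outside {0, 1, 2, NA}")
    return df


def write_weights(weights: pd.DataFrame, path) -> None:
    _write(weights, path)


def read_weights(path) -> pd.DataFrame:
    df = _read(path)
    need = {"snp_id", "effect_allele", "weight"}
    if not need <= set(df.columns):
        raise ValueError(f"weight TSV lacks columns: {sorted(need - set(df.columns))}")
    return df


def write_exposures(exposures: pd.DataFrame, path) -> None:
    _write(exposures.reset_index(), path)


def read_exposures(path) -> pd.DataFrame:
    return _read(path).set_index("subject_id")


def write_subsample_manifest(subsamples: Sequence[BalancedSubsample],
                             cohort: CohortTable, path) -> None:
    """Manifest TSV (replicate, subject_id, group, protocol) plus a JSON
    sidecar with the seeds and the accepted matching p-values."""
    ph = cohort.phenotypes.set_index("subject_id")
    rows: List[dict] = []
    for r, ss in enumerate(subsamples):
        for group, ids in (("T", ss.subject_ids_T), ("NT", ss.subject_ids_NT)):
            for sid in ids:
                rows.append({"replicate_index": r, "subject_id": sid,
                             "group": group,
                             "protocol": ph.loc[sid, "protocol"]})
    _write(pd.DataFrame(rows), path)
    sidecar = [{"replicate_index": r, "seed": ss.seed,
                "attempt_count": ss.attempt_count,
                "age_p": ss.age_p, "sex_p": ss.sex_p}
               for r, ss in enumerate(subsamples)]
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def write_cv_plan_json(plan: CVPlan, path) -> None:
    payload = {
        "scheme": plan.scheme, "seed": plan.seed,
        "folds": [{
            "outer_index": f.outer_index,
            "train_ids": list(f.train_ids),
            "test_ids": list(f.test_ids),
            "inner_folds": [[list(tr), list(va)] for tr, va in f.inner_folds],
        } for f in plan.folds],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def write_scores(scores: pd.DataFrame, path) -> None:
    _write(scores.reset_index(), path)


def write_predictions(frame: pd.DataFrame, path) -> None:
    _write(frame, path)
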