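"""End-to-end experiment orchestration.

One experiment = every legal combination of feature family, feature
manipulation and cross-validation scheme, run on each balanced bootstrap
replicate, permutation-tested, and aggregated by the 3-of-5 rule:

* regional sMRI families (ROIGM, ROIWM, ROISurface): linear SVM, with and
  without greedy forward selection, under LSO, LPO and 5-fold CV;
* voxel-wise families (VBGM, VBWM): linear SVM after robust PCA, under the
  three schemes;
* SNP dosages, eQTL scores and individual exposures: elastic-net logistic
  regression, outer LPO with inner 5-fold;
* PRS and ERS composites: single-feature logistic regression in a simple
  LPO scheme.

Feature manipulation is legal only where stated: PCA for voxel families,
forward selection for regional families, nothing for single scores.
The multimodal gate then admits modalities with at least 60 % significant
replicates; when none pass (the expected outcome under the null), no
multimodal model is trained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import balancing, cv, evaluation, models, scores, synthetic
from .types import (BootstrapReport, ClassifierSpec, CohortTable, EffectSpec,
                    MatchCriteria, ROI_FAMILIES, VOXEL_FAMILIES)

__all__ = ["PipelineConfig", "run_experiment_grid", "ExperimentResult",
           "PRESETS", "make_preset_cohort"]

#: Cohort shapes mirroring the study's modality sub-samples.
PRESETS = {
    # 23 T / 76 NT with imaging, three protocols (T split 14/3/6)
    "paper-smri": {"n_T": 23, "n_NT": 76, "protocol_mix": (14 / 23, 3 / 23, 6 / 23)},
    # 21 T / 54 NT with usable genotypes
    "paper-genetic": {"n_T": 21, "n_NT": 54, "protocol_mix": (1 / 3, 1 / 3, 1 / 3)},
    # 37 T / 97 NT passing the exposure-missingness filter
    "paper-environment": {"n_T": 37, "n_NT": 97, "protocol_mix": (1 / 3, 1 / 3, 1 / 3)},
}


#: Feature manipulation is legal only where stated: selection for regional
#: families, PCA for voxel families, nothing for score/low-dimensional data.
LEGAL_MANIPULATIONS = {
    **{f: ("none", "forward_selection") for f in ROI_FAMILIES},
    **{f: ("robust_pca",) for f in VOXEL_FAMILIES},
    **{f: ("none",) for f in ("SNP", "EQTL", "ENV", "SCORE")},
}


def check_manipulation(family: str, manipulation: str) -> None:
    legal = LEGAL_MANIPULATIONS.get(family)
    if legal is None:
        raise ValueError(f"unknown feature family {family!r}")
    if manipulation not in legal:
        raise ValueError(
            f"illegal combination: {manipulation!r} is not applicable to "
            f"the {family} family (legal: {legal})")


def make_preset_cohort(preset: str, seed: int) -> CohortTable:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    p = PRESETS[preset]
    return synthetic.generate_cohort(p["n_T"], p["n_NT"], p["protocol_mix"], seed)


@dataclass
class PipelineConfig:
    """Everything needed to re-run an experiment bit-identically."""

    seed: int = 0
    modalities: Sequence[str] = ("smri",)
    smri_families: Sequence[str] = ("ROIGM", "ROIWM", "ROISurface", "VBGM", "VBWM")
    roi_manipulations: Sequence[str] = ("none", "forward_selection")
    schemes: Sequence[str] = ("LSO", "LPO", "KFOLD")
    n_replicates: int = 5
    n_permutations: int = 1000
    alpha: float = 0.05
    min_significant_fraction: float = 0.6
    variance_target: float = 0.8
    retain_fraction: float = 0.1
    inner_k: int = 5
    outer_k: int = 5
    voxel_scale: int = 2000
    n_snps: int = 500
    effect: EffectSpec = field(default_factory=EffectSpec)
    preset: str = "paper-smri"
    svm_C: Optional[Sequence[float]] = None        # default: printed grid
    enet_l1: Optional[Sequence[float]] = None
    enet_lambda: Optional[Sequence[float]] = None
    output_dir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "effect" in raw:
            raw["effect"] = EffectSpec(**raw["effect"])
        return cls(**raw)

    def grids(self) -> cv.HyperparameterGrid:
        g = cv.default_grids()
        return cv.HyperparameterGrid(
            svm_C=tuple(self.svm_C) if self.svm_C else g.svm_C,
            enet_l1=tuple(self.enet_l1) if self.enet_l1 is not None else g.enet_l1,
            enet_lambda=(tuple(self.enet_lambda)
                         if self.enet_lambda is not None else g.enet_lambda),
        )


@dataclass
class ExperimentResult:
    reports: List[BootstrapReport]
    admitted_modalities: List[str]
    multimodal_trained: bool

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "modality": r.modality, "configuration": r.configuration,
            "mean_bac": float(np.mean([p.BAC for p in r.reports])),
            "n_significant": r.n_significant, "decision": r.decision,
        } for r in self.reports])


def _plan_for(scheme: str, subsample, cohort, config, seed, labels=None,
              by_protocol=True):
    if scheme == "LSO":
        return cv.build_lso_plan(subsample, cohort, config.inner_k, seed,
                                 labels=labels)
    if scheme == "LPO":
        return cv.build_lpo_plan(subsample, cohort, config.inner_k, seed,
                                 by_protocol=by_protocol, labels=labels)
    return cv.build_kfold_plan(subsample, cohort, config.outer_k,
                               config.inner_k, seed, labels=labels)


def _subsample_from_labels(lab: pd.Series) -> "BalancedSubsample":
    from .types import BalancedSubsample
    t = list(lab.index[lab == "T"])
    nt = list(lab.index[lab == "NT"])
    return BalancedSubsample(t, nt, attempt_count=1, age_p=1.0, sex_p=1.0,
                             seed=0)


def _make_plan_builder(scheme, cohort, config, seed, by_protocol=True):
    """labels -> CVPlan with the same scheme and seed; used by the
    permutation test to re-derive folds for permuted labels."""
    def build(lab: pd.Series):
        return _plan_for(scheme, _subsample_from_labels(lab), cohort,
                         config, seed, labels=lab, by_protocol=by_protocol)
    return build


def _run_configuration(spec, plan, feats, labels, prep, config, seed,
                       simple_logistic=False, plan_builder=None, strata=None):
    perm = evaluation.permutation_test_bac(
        spec, plan, feats, labels, config.n_permutations, seed, prep,
        simple_logistic=simple_logistic, plan_builder=plan_builder,
        strata=strata)
    if simple_logistic:
        res = models.fit_simple_lpo_logistic(feats, labels, plan)
    else:
        res = models.run_nested_cv(spec, plan, feats, labels, prep)
    return res, perm


def run_experiment_grid(config: PipelineConfig) -> ExperimentResult:
    """Execute the full experiment grid on a synthetic cohort.

    Generates the preset cohort and its modality data from the config
    seed, draws the bootstrap replicates, runs every legal combination on
    each replicate with a permutation test, aggregates per combination and
    applies the multimodal gate.
    """
    master = np.random.SeedSequence(config.seed)
    seeds = iter(int(c.generate_state(1)[0] % 2**31) for c in master.spawn(4096))
    cohort = make_preset_cohort(config.preset, next(seeds))
    grids = config.grids()
    svm_spec = ClassifierSpec("linear_svm", svm_C=grids.svm_C)
    enet_spec = ClassifierSpec("elastic_net", enet_l1=grids.enet_l1,
                               enet_lambda=grids.enet_lambda)
    logit_spec = ClassifierSpec("logistic")

    smri = genetic_dosages = weight_table = exposures = None
    if "smri" in config.modalities:
        smri = synthetic.generate_smri_features(
            cohort, config.effect, config.voxel_scale)
    if "genetic" in config.modalities:
        genetic_dosages, weight_table = synthetic.generate_genotypes(
            cohort, config.n_snps, effect=config.effect)
    if "environmental" in config.modalities:
        exposures = synthetic.generate_exposures(
            cohort, missing_rate=0.05, effect=config.effect)

    criteria = MatchCriteria(protocol_one_to_one="smri" in config.modalities)
    subsamples = balancing.bootstrap_subsamples(
        cohort, criteria, config.n_replicates, next(seeds))
    labels_all = cohort.phenotypes.set_index("subject_id")["transition"]

    reports: List[BootstrapReport] = []

    def aggregate(modality, configuration, results, perms):
        metrics = [evaluation.confusion_metrics(r.predictions) for r in results]
        p_values = [p.p_value for p in perms]
        decision, count = evaluation.aggregate_bootstraps(
            p_values, config.alpha, config.min_significant_fraction)
        reports.append(BootstrapReport(
            modality=modality, configuration=configuration, reports=metrics,
            permutation_p_values=p_values,
            train_bacs=[r.mean_train_bac for r in results],
            n_significant=count, decision=decision))

    if smri is not None:
        for family in config.smri_families:
            fam = smri[family]
            if family in ("ROIGM", "ROIWM"):
                from .features import scale_to_tiv
                fam = scale_to_tiv(fam)
            manipulations = (tuple((m, m == "forward_selection")
                                   for m in config.roi_manipulations)
                             if family in ROI_FAMILIES else (("robust_pca", None),))
            for manip_name, fs in manipulations:
                check_manipulation(family, manip_name)
                prep = models.PrepRecipe(
                    minmax=True, pca=(family in VOXEL_FAMILIES),
                    variance_target=config.variance_target,
                    forward_selection=bool(fs),
                    retain_fraction=config.retain_fraction)
                for scheme in config.schemes:
                    results, perms = [], []
                    for ss in subsamples:
                        plan_seed = next(seeds)
                        plan = _plan_for(scheme, ss, cohort, config, plan_seed)
                        feats = fam.values.loc[ss.subject_ids]
                        labels = labels_all.loc[ss.subject_ids]
                        strata = cohort.phenotypes.set_index(
                            "subject_id")["protocol"]
                        res, perm = _run_configuration(
                            svm_spec, plan, feats, labels, prep, config,
                            next(seeds),
                            plan_builder=_make_plan_builder(
                                scheme, cohort, config, plan_seed),
                            strata=strata)
                        results.append(res)
                        perms.append(perm)
                    aggregate("smri", f"{family}|{manip_name}|{scheme}",
                              results, perms)

    if genetic_dosages is not None:
        prs = scores.compute_prs(genetic_dosages.values, weight_table)
        panel = scores.synthetic_gene_panel(
            list(genetic_dosages.values.columns), seed=config.seed)
        egen = scores.compute_egen_panel(genetic_dosages.values, panel)
        genetic_runs = (
            ("SNP|elastic_net|LPO", genetic_dosages.values, enet_spec, False),
            ("EQTL|elastic_net|LPO", egen, enet_spec, False),
            ("PRS|logistic|simpleLPO", prs.to_frame(), logit_spec, True),
        )
        for configuration, feats_df, spec, simple in genetic_runs:
            results, perms = [], []
            for ss in subsamples:
                plan_seed = next(seeds)
                plan = cv.build_lpo_plan(ss, cohort, config.inner_k,
                                         plan_seed, by_protocol=False)
                feats = feats_df.loc[ss.subject_ids]
                labels = labels_all.loc[ss.subject_ids]
                prep = models.PrepRecipe(minmax=not simple)
                res, perm = _run_configuration(
                    spec, plan, feats, labels, prep, config, next(seeds),
                    simple_logistic=simple,
                    plan_builder=None if simple else _make_plan_builder(
                        "LPO", cohort, config, plan_seed, by_protocol=False))
                results.append(res)
                perms.append(perm)
            aggregate("genetic", configuration, results, perms)

    if exposures is not None:
        keep = scores.filter_exposure_missingness(exposures)
        rr = scores.default_ers_weights(config.seed)
        ers = scores.compute_ers(exposures.loc[keep], rr)
        complete = exposures.dropna()
        env_cohort = cohort.subset(list(keep))
        env_runs = [("ERS|logistic|simpleLPO", ers.to_frame(), logit_spec,
                     True, env_cohort)]
        if (complete.index.isin(cohort.ids_of("T")).sum() >= 2
                and complete.index.isin(cohort.ids_of("NT")).sum() >= 2):
            env_runs.append(("ENV|elastic_net|LPO", complete, enet_spec,
                             False, cohort.subset(list(complete.index))))
        for configuration, feats_df, spec, simple, sub_cohort in env_runs:
            env_criteria = MatchCriteria(protocol_one_to_one=False)
            env_subsamples = balancing.bootstrap_subsamples(
                sub_cohort, env_criteria, config.n_replicates, next(seeds))
            results, perms = [], []
            for ss in env_subsamples:
                plan_seed = next(seeds)
                plan = cv.build_lpo_plan(ss, sub_cohort, config.inner_k,
                                         plan_seed, by_protocol=False)
                feats = feats_df.loc[ss.subject_ids]
                labels = labels_all.loc[ss.subject_ids]
                prep = models.PrepRecipe(minmax=not simple)
                res, perm = _run_configuration(
                    spec, plan, feats, labels, prep, config, next(seeds),
                    simple_logistic=simple,
                    plan_builder=None if simple else _make_plan_builder(
                        "LPO", sub_cohort, config, plan_seed,
                        by_protocol=False))
                results.append(res)
                perms.append(perm)
            aggregate("environmental", configuration, results, perms)

    admitted = evaluation.multimodal_gate(reports) if reports else []
    result = ExperimentResult(reports, admitted, multimodal_trained=bool(admitted))
    if config.output_dir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: ExperimentResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.frame().to_csv(out / "results.tsv", sep="\t", index=False)
    for r in result.reports:
        tab = evaluation.summarize_replicates(
            r.reports, r.permutation_p_values, config.alpha)
        safe = r.configuration.replace("|", "_")
        tab.to_csv(out / f"table_{r.modality}_{safe}.tsv", sep="\t")
    manifest = {
        "config": {k: (asdict(v) if isinstance(v, EffectSpec) else
                       (list(v) if isinstance(v, (tuple, list)) else v))
                   for k, v in asdict(config).items()},
        "admitted_modalities": result.admitted_modalities,
        "multimodal_trained": result.multimodal_trained,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
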