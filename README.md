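# armsml

Evaluating whether baseline biomarkers predict transition to psychosis in
an At-Risk Mental State (ARMS) cohort — a tested, reusable implementation
of the full evaluation pipeline: matched balanced bootstrapped
subsampling, nested cross-validation under three site-aware schemes,
per-modality classifiers, and permutation-tested balanced accuracy with a
3-of-5 replicate significance rule.

## Who this is for

Researchers in clinical prognosis / biomarker evaluation who need a
leakage-free harness for small, demographically confounded, multi-scanner
cohorts — and who want every stage (from subsampling to the final
significance decision) reproducible from a single seed. Because clinical
high-risk data cannot usually be shared, the package ships a seeded
synthetic-cohort generator that emulates the study structure (subject
roster with age/sex/scan protocol/transition label, regional and
voxel-wise structural-MRI features with total intracranial volume, SNP
dosages with effect-size weight tables, and eight environmental exposures
with missingness), so the whole pipeline is testable end to end without
any download.

## The method

Subjects are labeled T (transitioned to a first episode of psychosis) or
NT (no transition within ≥ 2 years of follow-up). For each data modality:

1. **Balancing** — all T subjects are kept and an equal number of NT
   subjects is drawn by seeded rejection sampling until the groups are
   matched on age (two-sided Mann–Whitney U, p > 0.05) and sex
   (two-sided χ², p > 0.05), one-to-one per scanner protocol for imaging
   data. The subsampling is repeated to give 5 bootstrap replicates.
2. **Features** — regional volumes are scaled to total intracranial
   volume (TIV); every feature entering an SVM is min–max scaled to
   [0, 1] on the training rows; voxel-wise families are reduced by robust
   PCA (median/MAD standardization, components up to 80 % explained
   variance, capped at *n*/2); regional families optionally pass a greedy
   forward feature selection keeping the 10 % most predictive features by
   mean inner-fold balanced accuracy.
3. **Models & CV** — linear SVM (C = 2^l, l ∈ −5…4) for sMRI; logistic
   regression for single composite scores (polygenic risk score PRS,
   environmental risk score ERS); elastic-net logistic regression
   (l₁ ∈ 0:0.1:1, λ ∈ 0.01:0.01:1) for SNP, eQTL-score and exposure
   features. Hyperparameters are tuned in an inner stratified 5-fold
   cycle; generalization is measured on outer folds under LSO
   (leave-one-scan-protocol-out), LPO (leave-one-T/NT-pair-out, pair from
   the same protocol) or stratified 5-fold CV.
4. **Evaluation** — sensitivity, specificity, BAC = (SE + SP)/2,
   likelihood ratios and the diagnostic odds ratio from the out-of-fold
   confusion matrix; a label-permutation test of BAC > 50 % that re-runs
   the entire nested CV per permutation; a configuration is *predictive*
   only if ≥ 3 of 5 replicates are individually significant, and only
   modalities passing that gate would enter a multimodal model.

Composite scores: PRS = Σ dosage × GWAS log-odds weight; eGenScore = the
same sum over a gene's expression-associated SNPs (one score per
gene/tissue); ERS = Σ log relative risk over eight environmental factors
under an independence assumption, with subjects missing ≥ 2 of 8 factors
excluded.

## Worked example

```python
import armsml
from armsml import cv
from armsml.types import ClassifierSpec, EffectSpec

cohort = armsml.generate_cohort(23, 76, (14/23, 3/23, 6/23), seed=7)
subsample = armsml.balance_subsample(cohort, seed=7)   # 23 T + 23 NT
roigm = armsml.scale_to_tiv(
    armsml.generate_smri_features(
        cohort, EffectSpec(n_informative=5, cohens_d=1.0, seed=7),
        voxel_scale=1)["ROIGM"])
labels = cohort.phenotypes.set_index("subject_id")["transition"]
spec = ClassifierSpec("linear_svm", svm_C=cv.default_grids().svm_C)
plan = cv.build_lpo_plan(subsample, cohort, seed=17)
res = armsml.run_nested_cv(spec, plan,
                           roigm.values.loc[subsample.subject_ids],
                           labels.loc[subsample.subject_ids])
print(res.bac, res.mean_train_bac)
```

prints (from `examples/balance_and_crossvalidate.py`):

```
balanced subsample: 23 T + 23 NT (accepted after 1 draw(s); age p = 0.482, sex p = 0.134)
   LSO:  3 outer folds, out-of-fold BAC = 0.761, train BAC = 0.945
   LPO: 23 outer folds, out-of-fold BAC = 0.696, train BAC = 0.979
5-fold:  5 outer folds, out-of-fold BAC = 0.696, train BAC = 0.978
```

Out-of-fold BAC is the generalization estimate (0.5 = chance); the gap to
the train BAC is the resubstitution optimism that
`evaluation.overfitting_report` quantifies. More narrative scripts live in
`examples/` (cohort simulation, demographic tests, risk scores,
permutation significance), and a thin CLI mirrors the stages:
`armsml simulate | balance | plan | run | report | stats`.

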