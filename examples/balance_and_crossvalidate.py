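"""Matched subsampling and nested cross-validation of a linear SVM.

Draws a balanced, demographically matched subsample (all 23 transitioned
subjects plus 23 matched controls, one-to-one per scanner protocol),
builds the three nested CV schemes on it, and runs the tuned linear SVM
on TIV-scaled regional volumes under each scheme.
"""

import armsml
from armsml import cv
from armsml.types import ClassifierSpec, EffectSpec

cohort = armsml.generate_cohort(23, 76, (14 / 23, 3 / 23, 6 / 23), seed=7)
subsample = armsml.balance_subsample(cohort, seed=7)
print(f"balanced subsample: {len(subsample.subject_ids_T)} T + "
      f"{len(subsample.subject_ids_NT)} NT "
      f"(accepted after {subsample.attempt_count} draw(s); "
      f"age p = {subsample.age_p:.3f}, sex p = {subsample.sex_p:.3f})")

effect = EffectSpec(n_informative=5, cohens_d=1.0, seed=7)
roigm = armsml.scale_to_tiv(
    armsml.generate_smri_features(cohort, effect, voxel_scale=1)["ROIGM"])
labels = cohort.phenotypes.set_index("subject_id")["transition"]
feats = roigm.values.loc[subsample.subject_ids]
spec = ClassifierSpec("linear_svm", svm_C=cv.default_grids().svm_C)

for scheme, build in (("LSO", cv.build_lso_plan),
                      ("LPO", cv.build_lpo_plan),
                      ("5-fold", cv.build_kfold_plan)):
    plan = build(subsample, cohort, seed=17)
    res = armsml.run_nested_cv(spec, plan, feats,
                               labels.loc[subsample.subject_ids])
    print(f"{scheme:>6}: {len(plan.folds):2d} outer folds, "
          f"out-of-fold BAC = {res.bac:.3f}, "
          f"train BAC = {res.mean_train_bac:.3f}")
# The train-test gap is the resubstitution optimism the overfitting
# diagnostic quantifies; a d = 1.0 effect on 5 of 64 features typically
# yields an out-of-fold BAC well above the 0.5 chance level.
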