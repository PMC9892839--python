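# Methods

This note documents the models and procedures `armsml` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## The evaluation problem

The package evaluates *prognostic* classifiers: given baseline data from
help-seeking subjects in an At-Risk Mental State (ARMS), predict which of
them will transition to a first episode of psychosis (label T) and which
will not within at least two years of follow-up (NT). The statistical
difficulties this design has to survive are (a) a small minority class
(tens of T subjects), (b) demographic confounding (age and sex affect
both brain structure and transition risk), (c) scanner/site effects when
imaging data come from several acquisition protocols, and (d) the strong
optimism of any pipeline that tunes itself on the data it reports. The
pipeline answers them with matched balanced subsampling, site-aware
cross-validation, strictly in-fold preparation, and permutation-tested
significance aggregated over bootstrap replicates.

## Matched balanced subsampling

Every analysis runs on subsamples containing all available T subjects and
an equal number of NT subjects. The draw is rejection sampling: NT
subjects are drawn uniformly without replacement (stratified one-to-one
per scan protocol for imaging data) and the draw is accepted when a
two-sided Mann–Whitney U test on age and a two-sided uncorrected
chi-square test on sex both give p > 0.05. Rejection sampling was chosen
over nearest-neighbour or propensity matching because it makes the
acceptance criterion *exactly* the reported test, with no bias toward the
age-distribution tails; under matched generative marginals the median
accepted draw is the first one (a regression test guards this). The
subsampling is repeated five times from seeds spawned deterministically
off a master seed (`numpy.random.SeedSequence`); NT membership may
overlap between replicates but never within one. A degenerate sex table
(both groups single-sex) is treated as a perfect match (p = 1) inside the
matching loop, since the proportions are identical.

## Feature preparation

All preparation is fit on training rows only; interfaces take explicit
train/test pairs, so held-out information cannot reach a fit.

* **TIV scaling** (regional volume families): each of the 64 gray- or
  white-matter regional volumes is divided by the subject's total
  intracranial volume. Per-subject and stateless, hence applied once,
  cohort-wide. The TIV column is consumed; scaling twice is an error.
* **Min–max scaling**: per-feature (x − min)/(max − min) with min/max
  from the training rows. Held-out values may leave [0, 1] and are *not*
  clamped — clamping would discard margin information the linear SVM
  geometry uses. Constant training features map to 0.
* **Robust PCA** (voxel families): features are centered by their
  training median and scaled by their training raw MAD (MAD-zero
  features dropped), then the training matrix is eigendecomposed (via
  SVD, never forming the p×p covariance). The smallest k reaching 80 %
  cumulative explained variance is kept, truncated at ⌊n/2⌋ where n is
  the training size of the cycle being fit. A flag switches to classic
  mean/SD PCA. A low-rank-plus-sparse decomposition was rejected as the
  default for determinism and speed at this scale.
* **Greedy forward selection** (regional families): starting from the
  empty set, each step adds the feature maximizing mean inner-fold
  balanced accuracy of the linear SVM on the already-selected set plus
  the candidate, stopping at max(1, ⌊0.1·p⌋) features (64 → 6, 272 → 27);
  ties break to the lowest feature index. The fixed-cardinality reading
  ("the 10 % most predictive") is implemented; an alternative reading —
  keep only accuracy-improving additions, possibly stopping early — is
  noted but not used. Selection sees only outer-training rows.

## Classifiers and nested cross-validation

* **Linear SVM** (sMRI families): C-grid 2^l, l = −5…4 (10 values).
  Implemented as dual coordinate descent on the hinge-loss dual with the
  bias as an appended constant column (the liblinear formulation),
  compiled with numba; the test suite verifies coefficient agreement with
  `sklearn.svm.LinearSVC(loss="hinge")` to ~1e-6 at tight tolerance. The
  in-house solver exists because the permutation design below needs
  ~10⁵–10⁶ fits per calibration study; during the inner grid search the C
  path is solved warm-started (ascending C keeps the dual feasible) at a
  looser tolerance, since the search only ranks C values; the final refit
  uses the tight setting. Class weights are equal (class-weighted
  alternatives were explicitly not pursued), and class assignment uses
  the sign of the decision value.
* **Logistic regression** (single composite scores, PRS/ERS): unpenalized
  Newton-Raphson with a 1e-8 ridge on the Hessian so separable inputs
  stay finite; predicted label is T iff P(T) > 0.5 (strict, so a
  probability of exactly 0.5 goes to NT). Run in a *simple* (non-nested)
  leave-one-pair-out scheme — one feature, no hyperparameters.
* **Elastic-net logistic regression** (SNP, eQTL-score, exposure
  features): glmnet parameterization, l₁ ∈ 0:0.1:1 (11) ×
  λ ∈ 0.01:0.01:1 (100) = 1,100 combinations, delegated to
  `sklearn.linear_model.LogisticRegression(solver="saga")` with
  C = 1/(n·λ).

Nested CV: hyperparameters are chosen by mean balanced accuracy over
stratified inner folds (5 by default, fewer when a class is too small;
with one subject per class the inner cycle is empty and the deterministic
tie-break decides). Ties break to the smallest C, then the largest λ,
then the smallest l₁ — fixed so runs are bit-reproducible. The winner is
refit on the whole outer-training set; outer-test predictions are the
generalization estimate, and the outer-train resubstitution BAC feeds the
overfitting diagnostic (mean train−test gap with a bootstrap CI).

Outer schemes: **LSO** (one fold per scan protocol — the held-out scanner
is never seen in training), **LPO** (one fold per T/NT pair, the pair
drawn from the same protocol by seeded random pairing, so the test pair
shares a site and the training set keeps its per-protocol group
proportions; a protocol-free variant serves non-imaging modalities), and
stratified **5-fold**. Every subject appears in exactly one outer test
set; inner folds partition only the outer-training set (leakage is
asserted structurally in tests, plus a canary test showing that poisoning
held-out rows cannot change a fitted model).

## Significance: permutation test and the 3-of-5 rule

Per replicate, the hypothesis "out-of-fold BAC exceeds the 50 % chance
level" is tested by label permutation with the add-one estimator
p = (1 + #{BAC_perm ≥ BAC_obs})/(1 + B); the *entire* pipeline —
preparation, tuning, refit — is re-run per permutation so training-phase
optimism is part of the null. A feature/manipulation/scheme combination
is declared predictive only when at least ⌈0.6·R⌉ of its R replicates
(3 of 5) are individually significant at 5 %; only modalities with a
passing combination are admitted to a multimodal model, and with no
admission the pipeline reports that no multimodal model is trained. A
one-tailed exact Wilcoxon signed-rank test of the median replicate BAC
against 0.5 (enumeration over all 2^n sign assignments, midranks for
ties, chance-level values dropped) is available as a reporting
alternative; the permutation 3-of-5 rule is the primary path.

**Fold re-derivation under permutation.** The observed run's folds are
label-aligned: LPO test sets hold one T and one NT, training sets stay
balanced. If those folds are frozen while labels are permuted, same-class
test pairs and unbalanced training sets systematically depress the null
BAC (empirically to ≈ 0.40 on null data), which inflates the type-I rate
of the test to ≈ 9–10 %. Each permutation therefore re-derives the fold
assignment from the permuted labels with the same scheme and seed, and
permutations are stratified by scan protocol whenever the design matched
protocols — restoring exchangeability between the observed and permuted
runs (null BAC re-centers on 0.500). After this correction the test is
slightly *conservative* (empirical rejection ≈ 2–4 % at nominal 5 %),
which is the irreducible effect of tie mass in a discrete statistic (BAC
moves in steps of 1/46 here) under the add-one tie-counting estimator.
A frozen-plan variant remains available on the nested path.

## Composite risk scores

* **PRS** — Σ over SNPs of effect-allele dosage (0/1/2) × log-odds
  weight, optionally restricted to SNPs at or below an association
  p-value threshold (the threshold is a required configuration choice,
  with no default claimed to match any published pipeline). Missing
  dosages are imputed as 2·MAF when a MAF is supplied, otherwise the SNP
  is skipped with a logged warning.
* **eGenScore** — the same weighted sum restricted to one gene's
  expression-associated SNPs, one score per (gene, tissue); the synthetic
  panel spans 141 gene/tissue columns. Dosages are assumed pre-oriented
  to the weight table's effect allele; `validate_alleles` flags
  annotation mismatches instead of silently strand-flipping (strand QC
  belongs upstream).
* **ERS** — Σ over the eight environmental factors of log(relative risk
  of the subject's coded level), the additive form implied by the
  factors-independent assumption (the multiplicative RR product is the
  same score exponentiated). Missing factors contribute 0 (population
  average), but subjects missing ≥ 2 of 8 factors are excluded up front.
  The shipped relative-risk table is synthetic (plausible RR 1.5–3
  magnitudes), since published meta-analytic weights are not
  redistributable.

All three scores are linear in their weight tables and invariant to SNP
order; tests verify them against explicit per-subject loop oracles.

## The synthetic cohort generator

The generator emulates the structure — not the biology — of a clinical
high-risk study: ages truncated-normal(23, 4.5) on [14, 45], sex
Bernoulli(0.55 male), three scan protocols with a configurable mix
(default mirroring the imaging sub-sample's 14/3/6 split of T subjects),
NT follow-up ≥ 2 years. Cohort-shape presets mirror the modality
sub-samples (23 T/76 NT imaging; 21 T/54 NT genetic; 37 T/97 NT
environmental). Feature tables are Gaussian with unit within-group SD;
an `EffectSpec` injects a standardized mean shift of `cohens_d` on the
first `n_informative` features (0 = the null regime; tests verify ~5 %
t-test rejection under the null and recovery of the requested d at
n = 2000). Scanner effects are additive per-protocol feature offsets,
default 0.3 within-group SD — enough for the site-aware schemes to have
something to guard against. Voxel-wise families default to 2,000 columns;
the full voxel counts are a scale parameter, not a structural property.
Genotypes are binomial(2, MAF) with MAF uniform on (0.05, 0.5); a group
effect shifts the informative SNPs' allele frequency additively by
0.05·d in the T group. Exposures are coded risk levels (binary or
3-level) with baseline non-reference probability 0.3 and
missing-completely-at-random entries.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: spatial correlation among brain
regions, linkage disequilibrium among SNPs, informative missingness,
non-Gaussian feature distributions, multiplicative or interacting
scanner effects, and any genuine biological coupling between modalities.
The calibration results (null BAC centering, permutation-test validity,
signal recovery) are statements about the pipeline's statistical
machinery under a clean generative model, not about achievable prognostic
accuracy.

## Numerical and reproducibility choices

Problem sizes for the shipped calibration studies: 50 null cohorts for
BAC centering; 2,000 null cohorts × 200 permutations for the
permutation-test validity study (500 in the test suite); 20 repetitions ×
5 replicates × 20 permutations for signal recovery (B = 20 is the
smallest count at which one exceedance-free replicate can clear the 5 %
level, p = 1/21). Number of permutations for production runs defaults to
1,000 and is configurable. Every stochastic stage takes an explicit seed;
replicate and stage seeds are spawned from the master seed, so results
are independent of execution order. Degenerate inputs have defined
behavior: constant features scale to 0, MAD-zero features are dropped
before PCA, separable logistic fits are iteration-capped at the
prediction-equivalent limit, and undefined likelihood ratios are
reported as explicit infinities/NaN rather than silently finite numbers.

## Known limitations

The elastic-net path at the full 1,100-point grid is the one stage whose
permutation test is computationally heavy (it delegates to saga rather
than the in-house solvers); production-scale permutation counts there
call for patience or a reduced grid. The greedy forward selection
re-runs per permutation (it is label-dependent), making permutation
testing of selection-based configurations similarly expensive. The
two-way ANOVA appearing in demographic tables of the source study design
is not implemented (its raw inputs are unavailable); group comparisons
are limited to the four tests above.
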