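"""Composite genetic and environmental risk scores.

Computes a polygenic risk score (weighted sum of risk-allele dosages), a
panel of per-gene brain eQTL scores, and the additive-log-relative-risk
environmental score with its missingness filter, all on synthetic inputs.
"""

import armsml
from armsml import scores
from armsml.types import EffectSpec

cohort = armsml.generate_cohort(21, 54, seed=3)
dosages, weights = armsml.generate_genotypes(cohort, n_snps=500,
                                             effect=EffectSpec(seed=3))

prs = scores.compute_prs(dosages.values, weights, p_threshold=0.5)
print(f"PRS over {int((weights.p_value <= 0.5).sum())} SNPs passing the "
      f"threshold: mean {prs.mean():.3f}, sd {prs.std():.3f}")

panel = scores.synthetic_gene_panel(list(dosages.values.columns), seed=3)
egen = scores.compute_egen_panel(dosages.values, panel)
print(f"eQTL scores: {egen.shape[1]} gene/tissue columns "
      f"for {egen.shape[0]} subjects")

exposures = armsml.generate_exposures(cohort, missing_rate=0.1,
                                      effect=EffectSpec(seed=3))
kept = scores.filter_exposure_missingness(exposures)  # < 2 of 8 missing
print(f"exposure filter: {len(kept)} of {len(exposures)} subjects retained")

rr = scores.default_ers_weights(seed=3)
ers = scores.compute_ers(exposures.loc[kept], rr)
print(f"ERS (sum of log relative risks): mean {ers.mean():.3f}, "
      f"max {ers.max():.3f}; 0 means every factor at its reference level")
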