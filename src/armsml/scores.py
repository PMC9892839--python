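"""Composite genetic and environmental risk scores.

Three weighted-sum scores, all linear in their weight tables:

* **PRS** — polygenic risk score: sum over SNPs of the subject's effect-
  allele dosage (0/1/2) times the SNP's GWAS log-odds weight, optionally
  restricted to SNPs below an association p-value threshold.
* **eGenScore** — per-gene brain eQTL score: the same weighted sum
  restricted to the SNPs significantly associated with that gene's brain
  expression, one score per (gene, tissue) — a proxy for genetically
  regulated expression.
* **ERS** — environmental risk score: sum of log relative risks of the
  subject's coded exposure levels across the eight environmental risk
  factors, under the assumption that the factors act independently.
  Missing factors contribute 0 (population-average assumption) but a
  subject with too many missing factors is excluded beforehand by
  :func:`filter_exposure_missingness` (fewer than 2 of 8 missing).

Dosage files are assumed pre-oriented to the weight table's effect allele;
:func:`validate_alleles` flags annotation mismatches rather than silently
flipping strands (strand QC belongs upstream).
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .synthetic import EXPOSURE_FACTORS, default_exposure_levels

__all__ = [
    "compute_prs",
    "compute_egen_score",
    "compute_egen_panel",
    "filter_exposure_missingness",
    "compute_ers",
    "default_ers_weights",
    "synthetic_gene_panel",
    "validate_alleles",
]

logger = logging.getLogger(__name__)


def _weighted_sum(dosages: pd.DataFrame, weights: pd.DataFrame,
                  maf: Optional[Mapping[str, float]] = None) -> pd.Series:
    """Core weighted allele sum; missing dosages imputed as 2*MAF when a
    MAF is supplied, else the SNP is skipped for that subject."""
    w = weights.set_index("snp_id")["weight"]
    common = [s for s in w.index if s in dosages.columns]
    if not common:
        raise ValueError("no overlap between dosage columns and weight table")
    d = dosages[common].astype(float)
    if d.isna().any().any():
        if maf is not None:
            fill = pd.Series({s: 2.0 * maf[s] for s in common if s in maf})
            d = d.fillna(fill)
        missing_snps = d.columns[d.isna().any()]
        if len(missing_snps):
            logger.warning("skipping missing dosages without MAF for %d SNPs",
                           len(missing_snps))
            d = d.fillna(0.0)
    return d.mul(w.loc[common], axis=1).sum(axis=1)


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame,
                p_threshold: Optional[float] = None,
                maf: Optional[Mapping[str, float]] = None) -> pd.Series:
    """Polygenic risk score per subject (rows of ``dosages``).

    ``weights`` needs columns snp_id, weight and (if ``p_threshold`` is
    given) p_value; thresholding keeps SNPs with p_value <= threshold.
    """
    w = weights
    if p_threshold is not None:
        w = w[w["p_value"] <= p_threshold]
        if w.empty:
            raise ValueError(f"no SNPs pass p_threshold={p_threshold}")
    score = _weighted_sum(dosages, w, maf)
    score.name = "prs"
    return score


def compute_egen_score(dosages: pd.DataFrame, eqtl_weights: pd.DataFrame,
                       maf: Optional[Mapping[str, float]] = None) -> pd.Series:
    """eQTL score for one gene/tissue: weighted allele sum over the gene's
    expression-associated SNPs."""
    genes = eqtl_weights.get("gene_id")
    if genes is not None and genes.nunique() > 1:
        raise ValueError("weight table spans multiple genes; restrict first")
    return _weighted_sum(dosages, eqtl_weights, maf)


def compute_egen_panel(dosages: pd.DataFrame, panel: pd.DataFrame,
                       maf: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """One eQTL-score column per (gene, tissue) in ``panel``."""
    cols = {}
    for (gene, tissue), block in panel.groupby(["gene_id", "tissue"], sort=True):
        cols[f"{gene}@{tissue}"] = compute_egen_score(dosages, block, maf)
    return pd.DataFrame(cols, index=dosages.index)


def synthetic_gene_panel(snp_ids: List[str], n_genes: int = 141,
                         snps_per_gene: int = 3, seed: int = 0) -> pd.DataFrame:
    """A synthetic eQTL weight panel over the supplied SNPs (default 141
    genes across brain tissues, matching the scale of the real panel)."""
    rng = np.random.default_rng(seed)
    tissues = ("cortex", "cerebellum", "hippocampus")
    rows = []
    for g in range(n_genes):
        tissue = tissues[g % len(tissues)]
        chosen = rng.choice(snp_ids, size=min(snps_per_gene, len(snp_ids)),
                            replace=False)
        for s in chosen:
            rows.append({"snp_id": s, "gene_id": f"GENE{g:04d}",
                         "tissue": tissue,
                         "effect_allele": rng.choice(list("ACGT")),
                         "weight": rng.normal(0.0, 0.1),
                         "p_value": rng.uniform(0.0, 5e-4)})
    return pd.DataFrame(rows)


def validate_alleles(weights_a: pd.DataFrame, weights_b: pd.DataFrame) -> pd.Index:
    """Return SNP ids whose effect-allele annotations disagree between two
    weight tables (the caller decides what to do; nothing is flipped)."""
    a = weights_a.set_index("snp_id")["effect_allele"]
    b = weights_b.set_index("snp_id")["effect_allele"]
    common = a.index.intersection(b.index)
    return common[a.loc[common] != b.loc[common]]


def filter_exposure_missingness(exposures: pd.DataFrame,
                                max_missing: int = 1) -> pd.Index:
    """Subjects retained for the ERS analysis: at most ``max_missing``
    missing factors (default: fewer than 2 of the 8)."""
    n_missing = exposures.isna().sum(axis=1)
    return exposures.index[n_missing <= max_missing]


def default_ers_weights(seed: int = 0) -> Dict[str, Dict[int, float]]:
    """Per-factor relative risks by coded level (level 0 = reference, RR 1).

    These are plausible synthetic magnitudes (RR 1.5-3) standing in for the
    published meta-analytic estimates, which are not redistributable.
    """
    rng = np.random.default_rng(seed)
    weights: Dict[str, Dict[int, float]] = {}
    for factor in EXPOSURE_FACTORS:
        levels = default_exposure_levels(factor)
        rr = {0: 1.0}
        for lvl in range(1, levels):
            rr[lvl] = float(np.round(rng.uniform(1.5, 3.0) ** (lvl / (levels - 1)), 3))
        weights[factor] = rr
    return weights


def compute_ers(exposures: pd.DataFrame,
                rr_weights: Mapping[str, Mapping[int, float]]) -> pd.Series:
    """Environmental risk score: sum of log relative risks over the eight
    factors; missing factors contribute 0."""
    out = pd.Series(0.0, index=exposures.index, name="ers")
    for factor in exposures.columns:
        table = rr_weights[factor]
        col = exposures[factor]
        vals = np.zeros(len(col))
        notna = col.notna().to_numpy()
        for i, v in enumerate(col):
            if not notna[i]:
                continue
            lvl = int(v)
            if lvl not in table:
                raise ValueError(f"coded level {lvl} of {factor!r} absent "
                                 f"from the relative-risk table")
            vals[i] = math.log(table[lvl])
        out += vals
    return out
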