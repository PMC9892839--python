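"""Seeded synthetic ARMS cohorts and modality data.

The generators emulate the structure of a clinical high-risk (At-Risk
Mental State) study: a roster of subjects with age, sex, one of three scan
acquisition protocols and a transition label (T = transitioned to a first
episode of psychosis, NT = did not within >= 2 years of follow-up);
regional and voxel-wise structural-MRI feature tables with a total
intracranial volume (TIV) column; SNP dosage matrices with effect-size
weight tables; and eight environmental risk-factor exposures with
missing-at-random entries.

Group signal is controlled by :class:`~armsml.types.EffectSpec`: the first
``n_informative`` features of each table have their T/NT means separated by
``cohens_d`` within-group standard deviations (``cohens_d = 0`` is the null
regime). Scanner differences are emulated as an additive per-protocol
offset so the site-aware cross-validation schemes have something to guard
against.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CohortTable, EffectSpec, ModalityFeatures

__all__ = [
    "generate_cohort",
    "generate_smri_features",
    "generate_genotypes",
    "generate_exposures",
    "EXPOSURE_FACTORS",
    "default_exposure_levels",
]

PROTOCOLS = ("P1", "P2", "P3")

#: The eight environmental risk factors assessed at baseline.
EXPOSURE_FACTORS = (
    "tobacco", "cannabis", "migrant", "ethnic_minority",
    "urbanicity", "parental_age", "childhood_trauma", "season_of_birth",
)

# Number of risk levels per factor (level 0 = reference).
_FACTOR_LEVELS = {
    "tobacco": 2, "cannabis": 2, "migrant": 2, "ethnic_minority": 2,
    "urbanicity": 3, "parental_age": 3, "childhood_trauma": 2,
    "season_of_birth": 2,
}

AGE_MEAN, AGE_SD, AGE_LO, AGE_HI = 23.0, 4.5, 14.0, 45.0
P_MALE = 0.55
TIV_MEAN, TIV_SD = 1450.0, 110.0  # cm^3-scaled intracranial volume

SMRI_FAMILY_SIZES = {"ROIGM": 64, "ROIWM": 64, "ROISurface": 272}

#: Default scanner effect: additive per-protocol offset in within-group SDs.
DEFAULT_PROTOCOL_OFFSET_SD = 0.3


def default_exposure_levels(factor: str) -> int:
    return _FACTOR_LEVELS[factor]


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def generate_cohort(n_T: int, n_NT: int,
                    protocol_mix: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
                    seed: int = 0) -> CohortTable:
    """Generate a subject roster with ``n_T`` transitioned and ``n_NT``
    non-transitioned subjects.

    Ages are truncated-normal(23, 4.5) on [14, 45]; sex is Bernoulli(0.55)
    male; protocols are multinomial over ``protocol_mix``. NT subjects get
    follow-up >= 2 years (the label requires it); T subjects get a
    transition time within 2 years.
    """
    if n_T < 1 or n_NT < 1:
        raise ValueError("n_T and n_NT must both be >= 1")
    mix = np.asarray(protocol_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-8 or (mix < 0).any():
        raise ValueError("protocol_mix must be 3 nonnegative proportions summing to 1")
    rng = np.random.default_rng(seed)
    n = n_T + n_NT
    labels = np.array(["T"] * n_T + ["NT"] * n_NT)
    ages = _truncnorm(rng, AGE_MEAN, AGE_SD, AGE_LO, AGE_HI, n)
    sexes = np.where(rng.random(n) < P_MALE, "male", "female")
    protocols = rng.choice(PROTOCOLS, size=n, p=mix)
    followup = np.where(labels == "NT",
                        rng.uniform(2.0, 5.0, size=n),
                        rng.uniform(0.1, 2.0, size=n))
    ph = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age_years": ages,
        "sex": sexes,
        "protocol": protocols,
        "transition": labels,
        "followup_years": followup,
    })
    membership = {sid: frozenset({"smri", "genetic", "environmental"})
                  for sid in ph["subject_id"]}
    return CohortTable(ph, membership)


def _signal_shift(cohort: CohortTable, effect: EffectSpec, p: int,
                  sigma: float) -> np.ndarray:
    """Additive mean shift (subjects x features) for the informative block."""
    n = len(cohort)
    shift = np.zeros((n, p))
    k = min(effect.n_informative, p)
    if k and effect.cohens_d:
        is_t = (cohort.phenotypes["transition"] == "T").to_numpy()
        shift[is_t, :k] = effect.cohens_d * sigma
    return shift


def _protocol_offsets(cohort: CohortTable, rng: np.random.Generator, p: int,
                      sigma: float, offset_sd: float) -> np.ndarray:
    """Per-protocol additive offsets emulating scanner differences."""
    offsets = {proto: rng.normal(0.0, offset_sd * sigma, size=p)
               for proto in PROTOCOLS}
    proto = cohort.phenotypes["protocol"].to_numpy()
    return np.vstack([offsets[pr] for pr in proto])


def generate_smri_features(cohort: CohortTable, effect: EffectSpec,
                           voxel_scale: int = 2000,
                           protocol_offset_sd: float = DEFAULT_PROTOCOL_OFFSET_SD,
                           ) -> Dict[str, ModalityFeatures]:
    """Generate the five sMRI feature families.

    ROIGM/ROIWM (64 regional volumes each), ROISurface (272 surface
    measures) and two voxel-wise families at ``voxel_scale`` columns each
    (stand-ins for full voxel maps, whose count is a scale rather than a
    structural property). Every family carries a positive TIV series.
    """
    if voxel_scale < 1:
        raise ValueError("voxel_scale must be >= 1")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(effect.seed)
    n = len(cohort)
    ids = pd.Index(cohort.subject_ids, name="subject_id")
    tiv = pd.Series(np.abs(rng.normal(TIV_MEAN, TIV_SD, size=n)) + 1.0,
                    index=ids, name="tiv")
    sizes = dict(SMRI_FAMILY_SIZES)
    sizes["VBGM"] = voxel_scale
    sizes["VBWM"] = voxel_scale
    out: Dict[str, ModalityFeatures] = {}
    for family, p in sizes.items():
        base_mean = 5.0
        sigma = 1.0
        x = rng.normal(base_mean, sigma, size=(n, p))
        x += _signal_shift(cohort, effect, p, sigma)
        x += _protocol_offsets(cohort, rng, p, sigma, protocol_offset_sd)
        cols = [f"{family}_{j:04d}" for j in range(p)]
        out[family] = ModalityFeatures(
            pd.DataFrame(x, index=ids, columns=cols), family, tiv.copy())
    return out


def generate_genotypes(cohort: CohortTable, n_snps: int,
                       maf_range: Tuple[float, float] = (0.05, 0.5),
                       effect: EffectSpec = EffectSpec(),
                       ) -> Tuple[ModalityFeatures, pd.DataFrame]:
    """Generate a 0/1/2 dosage table and a SNP weight table.

    Dosages are binomial(2, MAF) per SNP with MAF uniform over
    ``maf_range``. Under a non-null effect, the informative SNPs' allele
    frequency is shifted additively by ``0.05 * cohens_d`` in the T group.
    The weight table covers every SNP (effect allele, log-odds weight,
    association p-value).
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(effect.seed)
    n = len(cohort)
    maf = rng.uniform(lo, hi, size=n_snps)
    is_t = (cohort.phenotypes["transition"] == "T").to_numpy()
    freq = np.tile(maf, (n, 1))
    k = min(effect.n_informative, n_snps)
    if k and effect.cohens_d:
        shifted = np.clip(maf[:k] + 0.05 * effect.cohens_d, 0.01, 0.99)
        freq[np.ix_(is_t, np.arange(k))] = shifted
    dosages = rng.binomial(2, freq)
    snp_ids = [f"rs{j:06d}" for j in range(n_snps)]
    ids = pd.Index(cohort.subject_ids, name="subject_id")
    dosage_table = ModalityFeatures(
        pd.DataFrame(dosages, index=ids, columns=snp_ids), "SNP")
    weights = pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": rng.choice(list("ACGT"), size=n_snps),
        "weight": rng.normal(0.0, 0.05, size=n_snps),
        "p_value": rng.uniform(0.0, 1.0, size=n_snps),
    })
    return dosage_table, weights


def generate_exposures(cohort: CohortTable, missing_rate: float = 0.0,
                       effect: EffectSpec = EffectSpec()) -> pd.DataFrame:
    """Generate the eight environmental risk-factor exposures.

    Each factor is a coded risk level (0 = reference). Entries are missing
    completely at random at ``missing_rate``. Under a non-null effect the T
    group's probability of a non-reference level is raised by
    ``0.1 * cohens_d`` (clipped) for the first ``n_informative`` factors.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(effect.seed)
    n = len(cohort)
    is_t = (cohort.phenotypes["transition"] == "T").to_numpy()
    base_p = 0.3  # baseline probability of any non-reference exposure level
    data = {}
    for j, factor in enumerate(EXPOSURE_FACTORS):
        levels = _FACTOR_LEVELS[factor]
        p_exposed = np.full(n, base_p)
        if j < effect.n_informative and effect.cohens_d:
            p_exposed[is_t] = np.clip(base_p + 0.1 * effect.cohens_d, 0.0, 0.95)
        exposed = rng.random(n) < p_exposed
        level = np.where(exposed, rng.integers(1, levels, size=n), 0).astype(float)
        if missing_rate > 0:
            level[rng.random(n) < missing_rate] = np.nan
        data[factor] = level
    ids = pd.Index(cohort.subject_ids, name="subject_id")
    return pd.DataFrame(data, index=ids)
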