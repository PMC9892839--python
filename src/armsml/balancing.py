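"""Group-balanced, demographically matched subsampling with bootstrapping.

Every machine-learning analysis runs on balanced subsamples: all available
transitioned (T) subjects plus an equal number of non-transitioned (NT)
subjects drawn so the two groups are statistically indistinguishable on age
(two-sided Mann-Whitney U, p > 0.05) and sex (two-sided chi-square,
p > 0.05), and — for imaging data — matched one-to-one on scan acquisition
protocol. The draw is seeded rejection sampling: protocol-stratified
uniform draws, re-drawn until both matching tests accept. The subsampling
is repeated to give independent bootstrap replicates (five by default);
NT membership may overlap across replicates but never within one.
"""

from __future__ import annotations

from typing import List

import numpy as np

from . import stats
from .types import BalancedSubsample, CohortTable, MatchCriteria

__all__ = ["balance_subsample", "bootstrap_subsamples"]


def _match_p_values(cohort: CohortTable, t_ids: List[str],
                    nt_ids: List[str]) -> tuple:
    ph = cohort.phenotypes.set_index("subject_id")
    age_t = ph.loc[t_ids, "age_years"].to_numpy()
    age_nt = ph.loc[nt_ids, "age_years"].to_numpy()
    age_p = stats.mann_whitney_u(age_t, age_nt).p_value
    sex_t = ph.loc[t_ids, "sex"]
    sex_nt = ph.loc[nt_ids, "sex"]
    table = [[int((sex_t == "male").sum()), int((sex_t == "female").sum())],
             [int((sex_nt == "male").sum()), int((sex_nt == "female").sum())]]
    try:
        sex_p = stats.chi_square_2x2(table).p_value
    except ValueError:
        # a zero sex margin means both groups are single-sex identically:
        # proportions are equal, treat as a perfect match
        sex_p = 1.0
    return age_p, sex_p


def _draw_nt(cohort: CohortTable, rng: np.random.Generator,
             one_to_one: bool) -> List[str]:
    ph = cohort.phenotypes
    t = ph[ph["transition"] == "T"]
    nt = ph[ph["transition"] == "NT"]
    if one_to_one:
        chosen: List[str] = []
        for proto, t_block in t.groupby("protocol"):
            pool = nt.loc[nt["protocol"] == proto, "subject_id"].to_numpy()
            need = len(t_block)
            if len(pool) < need:
                raise ValueError(
                    f"insufficient NT pool for protocol {proto}: "
                    f"need {need}, have {len(pool)}")
            chosen.extend(rng.choice(pool, size=need, replace=False))
        return chosen
    pool = nt["subject_id"].to_numpy()
    need = len(t)
    if len(pool) < need:
        raise ValueError(f"insufficient NT pool: need {need}, have {len(pool)}")
    return list(rng.choice(pool, size=need, replace=False))


def balance_subsample(cohort: CohortTable,
                      criteria: MatchCriteria = MatchCriteria(),
                      seed: int = 0) -> BalancedSubsample:
    """Draw one balanced subsample by seeded rejection sampling.

    All T subjects are retained; NT subjects are drawn uniformly
    (protocol-stratified when ``criteria.protocol_one_to_one``) and
    re-drawn until the Mann-Whitney age p-value and the chi-square sex
    p-value both exceed their thresholds, or ``max_attempts`` is exhausted.
    """
    rng = np.random.default_rng(seed)
    t_ids = cohort.ids_of("T")
    if not t_ids:
        raise ValueError("cohort has no T subjects")
    best = (-1.0, -1.0)
    for attempt in range(1, criteria.max_attempts + 1):
        nt_ids = _draw_nt(cohort, rng, criteria.protocol_one_to_one)
        age_p, sex_p = _match_p_values(cohort, t_ids, nt_ids)
        if age_p > criteria.age_p_threshold and sex_p > criteria.sex_p_threshold:
            return BalancedSubsample(
                subject_ids_T=list(t_ids), subject_ids_NT=list(nt_ids),
                attempt_count=attempt, age_p=age_p, sex_p=sex_p, seed=seed)
        if min(age_p, sex_p) > min(best):
            best = (age_p, sex_p)
    raise ValueError(
        f"matching failed after {criteria.max_attempts} attempts; "
        f"best attempt had age_p={best[0]:.4f}, sex_p={best[1]:.4f}")


def bootstrap_subsamples(cohort: CohortTable,
                         criteria: MatchCriteria = MatchCriteria(),
                         n_replicates: int = 5,
                         seed: int = 0) -> List[BalancedSubsample]:
    """Draw ``n_replicates`` independent balanced subsamples.

    Replicate seeds are derived deterministically from the master seed via
    :class:`numpy.random.SeedSequence` spawn keys, so the replicate set is
    reproducible and replicates are mutually independent. NT draws are
    without replacement within a replicate but replicates may overlap.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n_replicates)]
    return [balance_subsample(cohort, criteria, s) for s in child_seeds]
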