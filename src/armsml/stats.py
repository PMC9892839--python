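"""Group-comparison statistics used for demographic tables and matching.

These are the four tests the cohort work relies on: Pearson chi-square on a
2x2 contingency table (no continuity correction), Fisher's exact test
(two-sided, sum of smaller probabilities), the Mann-Whitney U test and the
two-sample t test (Welch or pooled). The chi-square deliberately omits the
Yates correction: the published sex-by-group comparisons (p = 0.380 for the
genetic sub-cohort, p = 0.411 for the environmental one) are reproduced only
without it, so the uncorrected statistic is fixed rather than configurable.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .types import TestResult

__all__ = [
    "chi_square_2x2",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "two_sample_t",
]


def _check_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: expected counts undefined")
    return arr


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    arr = _check_2x2(table)
    if np.allclose(arr[0] / arr[0].sum(), arr[1] / arr[1].sum()):
        # identical row proportions: statistic exactly 0 by construction
        return TestResult(0.0, 1.0, "chi_square")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(float(stat), float(p), "chi_square")


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test, two-sided by summing hypergeometric probabilities
    of all tables (margins fixed) no more probable than the observed one."""
    arr = _check_2x2(table)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(float(odds), float(min(p, 1.0)), "fisher_exact")


def _exact_mwu_p(x: np.ndarray, y: np.ndarray, u_x: float) -> float:
    """Two-sided exact Mann-Whitney p by enumerating rank assignments."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    total = 0
    extreme = 0
    mu = n1 * n2 / 2.0
    obs_dev = abs(u_x - mu)
    idx = range(n1 + n2)
    for comb in combinations(idx, n1):
        r1 = ranks[list(comb)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U (statistic reported for ``x``).

    Exact p by enumeration when n1+n2 <= 12 and there are no ties; otherwise
    the tie-corrected normal approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
    if not has_ties and len(pooled) <= 12:
        p = _exact_mwu_p(x, y, u_x)
    else:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue)
    return TestResult(u_x, min(p, 1.0), "mann_whitney_u")


def two_sample_t(x: Sequence[float], y: Sequence[float],
                 variant: str = "welch") -> TestResult:
    """Two-tailed independent-samples t test (Welch default, pooled optional)."""
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, f"t_{variant}")
        raise ValueError("zero variance in both samples: t undefined")
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.pvalue), f"t_{variant}")
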