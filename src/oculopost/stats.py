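"""Cohort-level inference: group comparison and attention correlation."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import InvalidInputError

EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    n1: int
    n2: int
    note: str = ""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided rank-sum (Mann-Whitney) test between independent groups.

    The exact null distribution is used whenever both groups have at most
    10 observations and the pooled data are tie-free; otherwise the normal
    approximation with mid-ranks, tie correction and continuity correction
    is used and noted in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) <= EXACT_MAX_N and len(b) <= EXACT_MAX_N and not has_ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic")
    note = "" if exact else "ties or large samples: mid-rank normal approximation"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal-approximation",
        n1=len(a),
        n2=len(b),
        note=note,
    )


def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidInputError("correlation undefined for a constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))
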