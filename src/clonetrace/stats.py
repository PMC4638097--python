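"""Exact 2x2 enrichment tests and fold ratios.

Three planned comparisons drive the biology here: functional-impact
enrichment on the trunk vs the germline background, TpC* context enrichment
on the trunk vs germline, and TpC* "timing" (trunk vs tumour-private
branches).  All use the two-sided Fisher exact test with the
point-probability (minimum-likelihood) two-sided rule, the convention of R's
``fisher.test``: the p-value sums hypergeometric probabilities of every
table with the observed margins whose point probability does not exceed the
observed table's (within a 1e-7 relative slack to absorb floating-point
ties).  Effect sizes are reported as ratios of proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

_REL_SLACK = 1e-7


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 comparison: counts, two-sided exact p, ratio of proportions."""

    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    fold: float  # proportion(row 1) / proportion(row 2); inf when denominator is 0
    group_labels: tuple[str, str] = ("group1", "group2")
    outcome_labels: tuple[str, str] = ("hit", "miss")
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "groups": list(self.group_labels),
            "outcomes": list(self.outcome_labels),
            "table": [list(r) for r in self.table],
            "p_value": self.p_value,
            "fold": self.fold,
            "degenerate": self.degenerate,
        }


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table of counts.

    A zero row or column margin makes the table degenerate: only one
    outcome is possible and p = 1.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    M = a + b + c + d
    n1 = a + b  # row-1 margin
    K = a + c   # column-1 margin
    if M == 0 or n1 in (0, M) or K in (0, M):
        return 1.0
    lo, hi = max(0, n1 + K - M), min(n1, K)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, M, K, n1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_SLACK)].sum())
    return min(p, 1.0)


def proportion_fold(k1: int, n1: int, k2: int, n2: int) -> float:
    """(k1/n1) / (k2/n2); returns +inf when k2 = 0 (no pseudocounts)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if k2 == 0:
        return math.inf
    return (k1 / n1) / (k2 / n2)


def fold_standard_error(k1: int, n1: int, k2: int, n2: int) -> float:
    """Delta-method standard error of the ratio of two binomial proportions.

    SE(fold) = fold * sqrt((1-p1)/k1 + (1-p2)/k2); infinite when either
    count is zero.
    """
    if k1 == 0 or k2 == 0:
        return math.inf
    p1, p2 = k1 / n1, k2 / n2
    fold = p1 / p2
    return fold * math.sqrt((1 - p1) / k1 + (1 - p2) / k2)


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int,
    group_labels: tuple[str, str] = ("group1", "group2"),
    outcome_labels: tuple[str, str] = ("hit", "miss"),
) -> EnrichmentResult:
    """Fisher test + fold for hits k1/n1 vs k2/n2."""
    table = ((k1, n1 - k1), (k2, n2 - k2))
    degenerate = n1 == 0 or n2 == 0 or (k1 + k2) in (0, n1 + n2)
    if n1 == 0 or n2 == 0:
        return EnrichmentResult(table, 1.0, math.nan, group_labels, outcome_labels, True)
    return EnrichmentResult(
        table,
        fisher_exact_2x2(table),
        proportion_fold(k1, n1, k2, n2),
        group_labels,
        outcome_labels,
        degenerate,
    )


def compare_functional(
    functional_flags: Sequence[bool],
    group1_idx: Sequence[int],
    group2_idx: Sequence[int],
    group_labels: tuple[str, str] = ("TUMOUR_SHARED", "ALL_SHARED"),
) -> EnrichmentResult:
    """Functional vs non-functional enrichment between two marker sets."""
    k1 = sum(1 for i in group1_idx if functional_flags[i])
    k2 = sum(1 for i in group2_idx if functional_flags[i])
    return compare_proportions(
        k1, len(group1_idx), k2, len(group2_idx),
        group_labels, ("functional", "non_functional"),
    )


def compare_tpc(
    tpc_flags: Sequence[Optional[bool]],
    group1_idx: Sequence[int],
    group2_idx: Sequence[int],
    group_labels: tuple[str, str] = ("TUMOUR_SHARED", "ALL_SHARED"),
) -> EnrichmentResult:
    """TpC* vs non-TpC* enrichment between two disjoint marker sets.

    Markers with unknown context (``None`` flag) are excluded from both
    sets.  The trunk-vs-germline and trunk-vs-private ("timing") presets of
    the analysis are both expressed through this comparison.
    """
    if set(group1_idx) & set(group2_idx):
        raise ValueError("the two marker sets must be disjoint")
    g1 = [i for i in group1_idx if tpc_flags[i] is not None]
    g2 = [i for i in group2_idx if tpc_flags[i] is not None]
    k1 = sum(1 for i in g1 if tpc_flags[i])
    k2 = sum(1 for i in g2 if tpc_flags[i])
    return compare_proportions(
        k1, len(g1), k2, len(g2), group_labels, ("TpC*", "non-TpC*")
    )
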