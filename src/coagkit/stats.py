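"""Replicate summaries, one-way ANOVA and Tukey HSD pairwise comparisons.

Clotting-time experiments run in small replicate sets (triplicates), and
published results often give only group summaries (mean ± SD, n).  This
module therefore supports both routes: ANOVA from raw replicate lists
(delegated to :func:`scipy.stats.f_oneway`) and an algebraically
identical ANOVA reconstructed from summary statistics alone, with Tukey
HSD pairwise comparisons computed from the pooled within-group mean
square and the studentized-range distribution (Tukey–Kramer for unequal
n).  The printed "±" values are taken to be sample SDs (n−1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one replicate group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError(
                f"group {self.label!r}: needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise InsufficientDataError(f"group {self.label!r}: SD must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey-adjusted pairwise comparison."""

    group_a: str
    group_b: str
    diff: float      # mean(b) − mean(a)
    p_adj: float
    significant: bool


def replicate_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean and sample SD (n−1 denominator) of one replicate set."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(
            f"replicate summary needs n >= 2 values, got {v.size}")
    return GroupSummary(label=label, n=int(v.size),
                        mean=float(v.mean()), sd=float(v.std(ddof=1)))


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA on raw replicate lists."""
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise InsufficientDataError("every group needs n >= 2")
    df_b = len(arrays) - 1
    df_w = sum(g.size for g in arrays) - len(arrays)
    # degenerate: zero within-group variance everywhere
    if all(g.std() == 0 for g in arrays):
        means = [g.mean() for g in arrays]
        if np.ptp(means) == 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
    F, p = sps.f_oneway(*arrays)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=float(p))


def anova_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from (mean, SD, n) per group.

    SS_between = Σ nᵢ(mᵢ − m̄)² with m̄ the n-weighted grand mean, and
    SS_within = Σ (nᵢ−1)sᵢ²; identical to the raw-data decomposition
    whenever the summaries are exact.
    """
    if len(summaries) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean for s in summaries], dtype=float)
    sd = np.array([s.sd for s in summaries], dtype=float)
    grand = float(np.sum(n * m) / np.sum(n))
    ss_b = float(np.sum(n * (m - grand) ** 2))
    ss_w = float(np.sum((n - 1) * sd**2))
    df_b = len(summaries) - 1
    df_w = int(np.sum(n)) - len(summaries)
    if ss_w == 0:
        if ss_b == 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0)
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def tukey_pairwise(summaries: Sequence[GroupSummary],
                   alpha: float = 0.05) -> list[PairwiseResult]:
    """Tukey HSD comparisons of all group pairs from summary statistics.

    Uses the pooled within-group mean square and the studentized-range
    distribution with k groups and Σnᵢ−k error degrees of freedom; the
    Tukey–Kramer standard error handles unequal group sizes.  With zero
    pooled variance, unequal means are reported as p = 0 and equal means
    as p = 1.
    """
    if len(summaries) < 2:
        raise InsufficientDataError("pairwise comparisons need >= 2 groups")
    k = len(summaries)
    df_w = int(sum(s.n for s in summaries)) - k
    msw = float(sum((s.n - 1) * s.sd**2 for s in summaries)) / df_w
    results = []
    for a, b in combinations(summaries, 2):
        diff = b.mean - a.mean
        if msw == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / a.n + 1.0 / b.n))
            q = abs(diff) / se
            p = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
        results.append(PairwiseResult(group_a=a.label, group_b=b.label,
                                      diff=float(diff), p_adj=p,
                                      significant=p < alpha))
    return results


def pairwise_table(results: Sequence[PairwiseResult]) -> pd.DataFrame:
    """Pairwise comparisons as a tidy table."""
    return pd.DataFrame(
        [{"group_a": r.group_a, "group_b": r.group_b, "diff": r.diff,
          "p_adj": r.p_adj, "significant": r.significant} for r in results]
    )
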