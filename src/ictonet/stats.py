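"""Nonparametric group comparisons.

Groups are compared with the Kruskal--Wallis rank test (tie-corrected H,
p from the chi-squared approximation with k-1 degrees of freedom, with an
optional permutation p-value for very small groups), followed by
Bonferroni-corrected pairwise rank-sum post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairwiseResult",
    "GroupComparison",
    "kruskal_wallis",
    "kruskal_wallis_h",
    "bonferroni_posthoc",
    "compare_groups",
]


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    p_value: float
    adjusted_alpha: float
    significant: bool


@dataclass
class GroupComparison:
    """One measure compared across named groups."""

    measure_name: str
    group_values: dict[str, list[float]]
    h_statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _validate_groups(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    return groups


def kruskal_wallis_h(groups) -> float:
    """Tie-corrected Kruskal--Wallis H statistic (0 if all values tie)."""
    groups = _validate_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0
    ranks = sps.rankdata(pooled)
    n = pooled.size
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return float(h / correction)


def kruskal_wallis(
    groups, method: str = "chi2", n_permutations: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """Kruskal--Wallis test across two or more groups.

    ``method="chi2"`` uses the chi-squared approximation (k-1 df);
    ``method="permutation"`` estimates the p-value by Monte-Carlo relabeling,
    preferable when group sizes are very small.  If every observation is
    identical the test is degenerate and (H, p) = (0, 1) is returned.
    """
    groups = _validate_groups(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h = kruskal_wallis_h(groups)
    if method == "chi2":
        # matches scipy.stats.kruskal
        p = float(sps.chi2.sf(h, df=len(groups) - 1))
        return h, p
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    sizes = np.cumsum([g.size for g in groups])[:-1]
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if kruskal_wallis_h(np.split(perm, sizes)) >= h - 1e-12:
            exceed += 1
    return h, (exceed + 1) / (n_permutations + 1)


def bonferroni_posthoc(
    groups, alpha: float = 0.05, labels: list[str] | None = None
) -> list[PairwiseResult]:
    """All pairwise rank-sum comparisons at the Bonferroni-adjusted level.

    Each pair is tested with a two-sided Mann--Whitney U test at
    ``alpha / C`` where C is the number of pairs (C = 1 leaves alpha
    unchanged).
    """
    groups = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pairs = list(combinations(range(len(groups)), 2))
    adj_alpha = alpha / len(pairs)
    out = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        if np.all(np.concatenate([a, b]) == a[0]):
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out.append(PairwiseResult(labels[i], labels[j], p, adj_alpha, p < adj_alpha))
    return out


def compare_groups(
    measure_name: str, group_values: dict[str, list[float]], alpha: float = 0.05
) -> GroupComparison:
    """Kruskal--Wallis omnibus test plus Bonferroni post hoc for one measure."""
    labels = list(group_values)
    groups = [group_values[k] for k in labels]
    h, p = kruskal_wallis(groups)
    pairwise = bonferroni_posthoc(groups, alpha=alpha, labels=labels)
    return GroupComparison(
        measure_name=measure_name,
        group_values={k: list(map(float, v)) for k, v in group_values.items()},
        h_statistic=h,
        p_value=p,
        pairwise=pairwise,
    )
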