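"""Group comparison statistics for computed image metrics.

Test choice follows the conventions of the source assays: equal-variance
two-tailed t test for scalar per-image metrics, Mann–Whitney U across
distributions (e.g. pooled orientation samples), Kruskal–Wallis for
multi-group scores, Fisher's exact test for penetrance counts. No
multiple-testing correction is applied; the chosen test is always recorded
alongside its result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "compare_groups", "TESTS"]

TESTS = ("t_equal_var", "mann_whitney", "kruskal_wallis", "fisher_exact")


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    test: str
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    group_ns: tuple[int, ...]


def _sem(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")


def compare_groups(
    values_by_group: dict, test: str, metric: str = "", two_sided: bool = True
) -> GroupComparison:
    """Run one named test on per-group value arrays (or a 2×2 count table).

    For ``fisher_exact`` pass ``{label_a: (hits, misses), label_b: ...}``.
    Variance-based tests require at least two values per group.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; allowed: {TESTS}")
    labels = tuple(values_by_group.keys())
    alternative = "two-sided" if two_sided else "greater"

    if test == "fisher_exact":
        if len(labels) != 2:
            raise ValueError("fisher_exact requires exactly two groups")
        table = np.array([values_by_group[k] for k in labels], dtype=int)
        if table.shape != (2, 2):
            raise ValueError("fisher_exact expects (hits, misses) per group")
        stat, p = stats.fisher_exact(table, alternative=alternative)
        totals = table.sum(axis=1)
        props = table[:, 0] / totals
        return GroupComparison(
            metric, test, float(stat), float(p), labels,
            tuple(float(x) for x in props), (float("nan"),) * 2,
            tuple(int(t) for t in totals),
        )

    groups = [np.asarray(values_by_group[k], dtype=float).ravel() for k in labels]
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")

    if test == "t_equal_var":
        if len(groups) != 2:
            raise ValueError("t test requires exactly two groups")
        if any(g.size < 2 for g in groups):
            raise ValueError("t test requires n >= 2 per group")
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=True,
                                  alternative=alternative)
    elif test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative=alternative)
    else:  # kruskal_wallis
        if len(groups) < 2:
            raise ValueError("Kruskal-Wallis requires >= 2 groups")
        stat, p = stats.kruskal(*groups)

    return GroupComparison(
        metric, test, float(stat), float(p), labels,
        tuple(float(np.mean(g)) for g in groups),
        tuple(_sem(g) for g in groups),
        tuple(int(g.size) for g in groups),
    )
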