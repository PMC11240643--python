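"""Nonparametric comparison machinery for the group-size analysis.

All group comparisons use the Mann–Whitney U test (chosen over parametric
alternatives because variances are heterogeneous across stocking
densities).  Within one statistic and one window, the six pairwise
comparisons between the four group sizes form a Bonferroni family;
significance letters summarise the adjusted results as in standard
box-plot annotation (groups sharing a letter are not significantly
different).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "TestResult",
    "PairwiseResult",
    "mann_whitney_u",
    "bonferroni",
    "pairwise_comparisons",
    "comparison_table",
    "significance_letters",
]

#: largest product n_x * n_y for which the exact null distribution is used
EXACT_LIMIT = 400


@dataclass
class TestResult:
    statistic_u: float
    p_raw: float
    n_x: int
    n_y: int
    alternative: str
    method: str
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.statistic_u <= self.n_x * self.n_y:
            raise DataError(f"U={self.statistic_u} outside [0, {self.n_x * self.n_y}]")
        if not 0 <= self.p_raw <= 1:
            raise DataError(f"p={self.p_raw} outside [0, 1]")

    @property
    def p(self) -> float:
        """Adjusted p-value when present, else the raw one."""
        return self.p_raw if self.p_adjusted is None else self.p_adjusted


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test with automatic exact/approximate method choice.

    The exact null distribution of U is used for tie-free samples with
    ``n_x * n_y <= 400``; otherwise the normal approximation with midrank
    tie correction and continuity correction.  U is reported for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise DataError(f"unknown alternative {alternative!r}")
    exact = not _has_ties(x, y) and x.size * y.size <= EXACT_LIMIT
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        statistic_u=float(res.statistic),
        p_raw=float(res.pvalue),
        n_x=int(x.size),
        n_y=int(y.size),
        alternative=alternative,
        method=method,
    )


def bonferroni(p_values: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Multiply each p-value by the family size, capping at 1.

    ``family_size`` defaults to ``len(p_values)``; passing it explicitly
    supports correcting a subset of a larger declared family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise DataError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else int(family_size)
    if m < 1:
        raise DataError("family size must be >= 1")
    return np.minimum(p * m, 1.0)


@dataclass
class PairwiseResult:
    """All unordered pairwise tests for one statistic in one window."""

    metric: str
    window: str
    pairs: list[tuple[int, int]]
    tests: list[TestResult]
    letters: dict[int, str]
    group_sizes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [a for a, _ in self.pairs],
                "group_b": [b for _, b in self.pairs],
                "p_raw": [t.p_raw for t in self.tests],
                "p_adjusted": [t.p_adjusted for t in self.tests],
                "method": [t.method for t in self.tests],
            }
        )


def significance_letters(
    groups: Sequence[int],
    pairs: Sequence[tuple[int, int]],
    p_adjusted: Sequence[float],
    group_means: dict[int, float],
    alpha: float = 0.05,
) -> dict[int, str]:
    """Compact letter display from pairwise adjusted p-values.

    Maximal cliques of the "not significantly different" graph receive one
    letter each, ordered by the clique's lowest group mean; every group is
    labelled with the letters of the cliques containing it.
    """
    ns = {frozenset(p) for p, padj in zip(pairs, p_adjusted) if padj >= alpha}

    def is_clique(subset: tuple[int, ...]) -> bool:
        return all(frozenset(c) in ns for c in itertools.combinations(subset, 2))

    cliques: list[tuple[int, ...]] = []
    for size in range(len(groups), 0, -1):
        for subset in itertools.combinations(groups, size):
            if is_clique(subset) and not any(set(subset) <= set(c) for c in cliques):
                cliques.append(subset)
    cliques.sort(key=lambda c: min(group_means[g] for g in c))
    labels = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            labels[g] += letter
    return labels


def _metric_values(records, metric: str, window: str) -> dict[int, np.ndarray]:
    attr = {
        ("mean", "flop"): "mean_activity_flop",
        ("mean", "llop"): "mean_activity_llop",
        ("high_sum", "flop"): "high_activity_sum_flop",
        ("high_sum", "llop"): "high_activity_sum_llop",
    }.get((metric, window))
    if attr is None:
        raise DataError(f"unknown metric/window combination ({metric!r}, {window!r})")
    by_group: dict[int, list[float]] = {}
    for r in records:
        value = getattr(r, attr)
        if value is None:
            raise DataError(f"{r.gondola_id}: statistic {attr} not computed")
        by_group.setdefault(r.group_size, []).append(value)
    return {g: np.asarray(v) for g, v in by_group.items()}


def pairwise_comparisons(
    records: Sequence,
    metric: str = "mean",
    window: str = "llop",
    alpha: float = 0.05,
    family_size: int | None = None,
    alternative: str = "two-sided",
) -> PairwiseResult:
    """Mann–Whitney tests between all group-size pairs, Bonferroni adjusted.

    The correction family defaults to the number of pairs within this
    metric/window (6 when four group sizes are present); pass
    ``family_size`` to correct jointly over, e.g., both windows.  Groups
    with fewer than two gondolas are excluded with a warning.
    """
    by_group = _metric_values(records, metric, window)
    for g in [g for g, v in by_group.items() if len(v) < 2]:
        warnings.warn(f"group size {g} has < 2 gondolas; excluded from comparisons")
        del by_group[g]
    groups = sorted(by_group)
    if len(groups) < 2:
        raise DataError("need at least two group sizes with >= 2 gondolas")
    pairs = list(itertools.combinations(groups, 2))
    tests = [
        mann_whitney_u(by_group[a], by_group[b], alternative=alternative) for a, b in pairs
    ]
    adjusted = bonferroni([t.p_raw for t in tests], family_size or len(pairs))
    for t, padj in zip(tests, adjusted):
        t.p_adjusted = float(padj)
    means = {g: float(by_group[g].mean()) for g in groups}
    letters = significance_letters(groups, pairs, adjusted, means, alpha=alpha)
    return PairwiseResult(
        metric=metric, window=window, pairs=pairs, tests=tests, letters=letters,
        group_sizes=groups,
    )


def comparison_table(
    records: Sequence,
    metric: str = "mean",
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Both windows side by side, mirroring the published table layout."""
    flop = pairwise_comparisons(records, metric, "flop", alpha, family_size)
    llop = pairwise_comparisons(records, metric, "llop", alpha, family_size)
    return pd.DataFrame(
        {
            "group_a": [a for a, _ in flop.pairs],
            "group_b": [b for _, b in flop.pairs],
            "p_flop": [t.p_adjusted for t in flop.tests],
            "p_llop": [t.p_adjusted for t in llop.tests],
            "method": [t.method for t in flop.tests],
        }
    )
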