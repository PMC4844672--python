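"""Shared statistics: rank tests, correlation, and decile machinery.

The Mann-Whitney test uses the exact null distribution (full enumeration over
rank assignments) when both samples are small and tie-free, and the normal
approximation with tie and continuity corrections otherwise — scipy's
implementation provides both paths.  No multiple-testing correction is applied
across score windows by default (each window is tested at plain p < alpha);
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence, TypeVar

import numpy as np
from scipy import stats

T = TypeVar("T")

EXACT_MAX_N = 8  # exact Mann-Whitney path when both samples <= this and tie-free


@dataclass
class TestReport:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    alternative: str
    n_x: int
    n_y: int
    group_labels: tuple = ("x", "y")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestReport:
    """Mann-Whitney U test (mid-rank ties).

    Exact p by enumeration when both n <= 8 with no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not _has_ties(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestReport(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=alternative,
        n_x=int(x.size),
        n_y=int(y.size),
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Pearson correlation with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a variable")
    res = stats.pearsonr(x, y)
    return TestReport(
        test="pearson",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative="two-sided",
        n_x=int(x.size),
        n_y=int(x.size),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional across-window correction)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


@dataclass
class DecilePartition:
    """Ten ordered groups of records, ascending in the sort key."""

    groups: List[List] = field(default_factory=list)
    key_label: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) != 10:
            raise ValueError("a decile partition has exactly 10 groups")


def _tiebreak(record) -> tuple:
    region = getattr(record, "region", None)
    if region is not None:
        rank = region.rank if region.rank is not None else 0
        return (rank, region.id or "", region.chrom, region.start)
    return (0, str(record))


def decile_partition(
    records: Sequence[T], key: Callable[[T], float], key_label: str = ""
) -> DecilePartition:
    """Split records into 10 near-equal groups ascending in ``key``.

    Sizes differ by at most one; the remainder goes to the lowest deciles.
    Ties are broken by region rank then id for determinism.
    """
    n = len(records)
    if n < 10:
        raise ValueError(f"need >= 10 records for a decile partition, got {n}")
    ordered = sorted(records, key=lambda r: (key(r), _tiebreak(r)))
    base, rem = divmod(n, 10)
    groups: List[List] = []
    pos = 0
    for d in range(10):
        size = base + (1 if d < rem else 0)
        groups.append(list(ordered[pos : pos + size]))
        pos += size
    return DecilePartition(groups=groups, key_label=key_label)


def extreme_decile_compare(
    records: Sequence[T],
    key: Callable[[T], float],
    value: Callable[[T], float],
    alternative: str = "two-sided",
) -> TestReport:
    """Mann-Whitney on ``value`` between the first and last decile of the
    ``key`` ordering (e.g. CFR across extreme best-score deciles)."""
    partition = decile_partition(records, key)
    lo = [value(r) for r in partition.groups[0]]
    hi = [value(r) for r in partition.groups[9]]
    report = mann_whitney_u(lo, hi, alternative=alternative)
    report.group_labels = ("first_decile", "last_decile")
    return report
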