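"""Open/closed chromatin classification of bound regions and the relation of
accessibility to occupancy fold reduction.

A bound region counts as *open* when its centred half — the middle 50% of the
region — is entirely covered by the union of DNase-hypersensitive intervals;
a single uncovered base breaks openness.  Quantitative DHS signal over a
region uses the same area definition as ChIP coverage (per-base sum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import CoverageTrack, GenomicInterval, merge_intervals, region_coverage
from .stats import TestReport, decile_partition, extreme_decile_compare, pearson_r


@dataclass
class OpenChromatinSet:
    """Merged DNase-hypersensitive (open) intervals."""

    intervals: List[GenomicInterval]
    source: str = ""

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals) if self.intervals else []


@dataclass
class AccessibilityRecord:
    """Accessibility state and DHS signal of one bound region."""

    region: GenomicInterval
    open: bool
    dhs_signal: float
    cfr: float


def centred_half(region: GenomicInterval) -> GenomicInterval:
    """The middle 50% of a region: [start + len//4, end - len//4)."""
    quarter = len(region) // 4
    return GenomicInterval(region.chrom, region.start + quarter, region.end - quarter)


def is_open_region(region: GenomicInterval, open_set: OpenChromatinSet) -> bool:
    """True iff the region's centred half is entirely covered by open intervals."""
    if len(region) < 2:
        raise ValueError("region must be at least 2 bp")
    half = centred_half(region)
    pos = half.start
    # merged intervals are sorted and disjoint: walk them left to right
    for iv in open_set.intervals:
        if iv.chrom != half.chrom or iv.end <= pos:
            continue
        if iv.start > pos:
            return False
        pos = iv.end
        if pos >= half.end:
            return True
    return pos >= half.end


def region_dhs_signal(region: GenomicInterval, dhs_track: CoverageTrack) -> float:
    """Quantitative DHS signal over a region (per-base sum, as for ChIP)."""
    return region_coverage(dhs_track, region)


def build_accessibility_records(
    cfr_records,
    open_set: OpenChromatinSet,
    dhs_track: Optional[CoverageTrack] = None,
) -> List[AccessibilityRecord]:
    """Combine CFR records with openness calls and optional DHS signal."""
    out = []
    for rec in cfr_records:
        signal = (
            region_dhs_signal(rec.region, dhs_track) if dhs_track is not None else 0.0
        )
        out.append(
            AccessibilityRecord(
                region=rec.region,
                open=is_open_region(rec.region, open_set),
                dhs_signal=signal,
                cfr=rec.cfr,
            )
        )
    return out


def fraction_closed_by_decile(records: Sequence[AccessibilityRecord]) -> np.ndarray:
    """Fraction of closed regions per CFR decile (decile 0 = lowest CFR)."""
    partition = decile_partition(records, key=lambda r: r.cfr)
    return np.array(
        [sum(not r.open for r in grp) / len(grp) for grp in partition.groups]
    )


@dataclass
class CorrelationReport:
    """Pearson CFR-vs-DHS correlation plus the extreme-DHS-decile rank test."""

    pearson: TestReport
    r: float
    r_squared: float
    extreme_decile: TestReport


def cfr_vs_dhs(
    records: Sequence[AccessibilityRecord], log10: bool = False
) -> CorrelationReport:
    """Correlate CFR with quantitative DHS signal.

    Pearson r (with r^2 and the two-sided t-transform p-value) on raw values
    by default (``log10=True`` transforms both via log10(x+1)), plus a
    Mann-Whitney comparison of CFR between the lowest- and highest-DHS
    deciles.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records")
    cfr = np.array([r.cfr for r in records], dtype=float)
    dhs = np.array([r.dhs_signal for r in records], dtype=float)
    if not (np.isfinite(cfr).all() and np.isfinite(dhs).all()):
        raise ValueError("non-finite values")
    if log10:
        cfr, dhs = np.log10(cfr + 1), np.log10(dhs + 1)
    report = pearson_r(cfr, dhs)
    extreme = extreme_decile_compare(
        list(records), key=lambda r: r.dhs_signal, value=lambda r: r.cfr
    )
    return CorrelationReport(
        pearson=report,
        r=report.statistic,
        r_squared=report.statistic**2,
        extreme_decile=extreme,
    )
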