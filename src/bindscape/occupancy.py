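"""Extended-read coverage, two-step normalization, and the coverage fold
reduction (CFR) statistic.

The comparison of genotype-level ChIP-seq occupancy proceeds in two steps:

1. *Intra-genotype*: coverages of bound regions in replicate 2 are regressed
   (through the origin) on replicate 1; the slope ``m`` rescales replicate 2
   and the replicates are fused, ``fused = (rep1 + rep2/m) / 2``.
2. *Inter-genotype*: background peaks called in the untransformed control
   sample (a rudimentary cutoff-based peak finder, default cutoff 20) carry no
   genotype-specific signal, so regressing fused-genotype coverage on control
   coverage over them estimates the relative sequencing depth ``m'``; dividing
   the fused track by ``m'`` puts both genotypes on the control's scale.

The per-region CFR is then the ratio of normalized reference coverage over
normalized mutant coverage.  Regions whose mutant coverage is below the
equivalent of a single extended read are capped at a fixed CFR (default 300)
to avoid unstable or infinite ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CoverageTrack, GenomicInterval, region_coverage

DEFAULT_FRAGMENT_LENGTH = 130
DEFAULT_BACKGROUND_CUTOFF = 20.0
DEFAULT_CFR_CAP = 300.0


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped read reduced to its 5' position and orientation."""

    chrom: str
    pos: int  # 0-based 5' end
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError("read position must be >= 0")


@dataclass
class ScaleFactors:
    """Fitted normalization coefficients with basic diagnostics."""

    m: float  # intra-genotype replicate slope
    m_prime: float  # inter-genotype depth slope vs control
    n_replicate_points: int = 0
    n_background_peaks: int = 0
    replicate_residual_rms: float = float("nan")
    background_residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        if self.m <= 0 or self.m_prime <= 0:
            raise ValueError("scale factors must be positive")


@dataclass
class CFRRecord:
    """Per-region normalized coverages and coverage fold reduction."""

    region: GenomicInterval
    cov_ref: float
    cov_alt: float
    cfr: float
    capped: bool

    def __post_init__(self) -> None:
        if self.cfr <= 0:
            raise ValueError("CFR must be positive")


def read_reads_bed(path, chrom_lengths) -> List[ReadAlignment]:
    """Read aligned reads from 6-column BED (strand in column 6).

    The 5' end is ``start`` for + reads and ``end - 1`` for - reads.
    """
    from .core import BedParseError

    reads: List[ReadAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}: line {lineno}: expected 6 columns")
            chrom, strand = fields[0], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if chrom not in chrom_lengths:
                raise BedParseError(
                    f"{path}: line {lineno}: undeclared chromosome {chrom!r}"
                )
            pos = start if strand == "+" else end - 1
            reads.append(ReadAlignment(chrom, pos, strand))
    return reads


def extend_reads(
    reads: Sequence[ReadAlignment],
    chrom_lengths: Dict[str, int],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
) -> CoverageTrack:
    """Per-base count of reads extended to ``fragment_length`` bp.

    Each read contributes +1 over ``fragment_length`` bases starting at its 5'
    end in read orientation (a + read covers [pos, pos+L), a - read covers
    (pos-L, pos]), truncated at chromosome edges.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    track = CoverageTrack(chrom_lengths)
    # difference-array accumulation: O(reads + genome)
    diffs = {c: np.zeros(n + 1, dtype=np.float64) for c, n in chrom_lengths.items()}
    for read in reads:
        if read.chrom not in chrom_lengths:
            raise ValueError(f"read on undeclared chromosome {read.chrom!r}")
        n = chrom_lengths[read.chrom]
        if read.pos >= n:
            raise ValueError(
                f"read at {read.chrom}:{read.pos} outside chromosome (length {n})"
            )
        if read.strand == "+":
            s, e = read.pos, min(read.pos + fragment_length, n)
        else:
            s, e = max(read.pos - fragment_length + 1, 0), read.pos + 1
        diffs[read.chrom][s] += 1.0
        diffs[read.chrom][e] -= 1.0
    for c in chrom_lengths:
        track.data[c] = np.cumsum(diffs[c][:-1])
    return track


def rudimentary_peak_find(
    track: CoverageTrack,
    cutoff: float = DEFAULT_BACKGROUND_CUTOFF,
    min_gap: int = 0,
) -> List[GenomicInterval]:
    """Maximal runs of positions with signal >= cutoff, one interval per run.

    Runs separated by fewer than ``min_gap`` sub-cutoff bases are merged
    (``min_gap=0`` disables merging).  Used on the control sample to call
    background peaks for inter-genotype normalization.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    peaks: List[GenomicInterval] = []
    for chrom in track.chrom_lengths:
        above = track.data[chrom] >= cutoff
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[0::2], edges[1::2]
        if min_gap > 0 and starts.size > 1:
            keep_s, keep_e = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s - keep_e[-1] < min_gap:
                    keep_e[-1] = e
                else:
                    keep_s.append(s)
                    keep_e.append(e)
            starts, ends = np.array(keep_s), np.array(keep_e)
        rank0 = len(peaks)
        peaks.extend(
            GenomicInterval(chrom, int(s), int(e), id=f"bg_{chrom}_{i}", rank=rank0 + i)
            for i, (s, e) in enumerate(zip(starts, ends))
        )
    return peaks


def _origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("cannot fit slope: all predictor values are zero")
    return float(np.dot(x, y) / denom)


def fit_replicate_scale(
    cov_pairs: Sequence[Tuple[float, float]],
    fit_intercept: bool = False,
) -> float:
    """Slope ``m`` of replicate-2 coverage regressed on replicate-1 coverage.

    Least squares through the origin by default (no signal in one replicate
    implies none in the other); ``fit_intercept=True`` frees the intercept.
    """
    if len(cov_pairs) < 2:
        raise ValueError("need >= 2 coverage pairs")
    x = np.asarray([p[0] for p in cov_pairs], dtype=float)
    y = np.asarray([p[1] for p in cov_pairs], dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("coverages must be non-negative")
    if fit_intercept:
        slope, _ = np.polyfit(x, y, 1)
        return float(slope)
    return _origin_slope(x, y)


def fuse_replicates(
    track1: CoverageTrack,
    track2: CoverageTrack,
    m: float,
    symmetric: bool = False,
) -> CoverageTrack:
    """Fuse two replicate tracks into one normalized track.

    Default (reference-anchored): ``fused = (rep1 + rep2/m) / 2`` with rep1 as
    the reference replicate.  ``symmetric=True`` instead rescales both
    replicates to their geometric-mean depth, ``fused = (rep1*sqrt(m) +
    rep2/sqrt(m)) / 2``; both conventions leave a genotype-vs-itself
    normalization at the identity.
    """
    if m <= 0:
        raise ValueError("m must be > 0")
    if not track1.same_namespace(track2):
        raise ValueError("replicate tracks have mismatched chromosome namespaces")
    fused = CoverageTrack(track1.chrom_lengths)
    for c in fused.chrom_lengths:
        if symmetric:
            r = np.sqrt(m)
            fused.data[c] = (track1.data[c] * r + track2.data[c] / r) / 2.0
        else:
            fused.data[c] = (track1.data[c] + track2.data[c] / m) / 2.0
    return fused


def fit_genotype_scale(
    fused_track: CoverageTrack,
    control_track: CoverageTrack,
    background_peaks: Sequence[GenomicInterval],
    fit_intercept: bool = False,
) -> float:
    """Depth coefficient ``m'``: fused-genotype coverage regressed on control
    coverage over control-called background peaks (through the origin)."""
    if not background_peaks:
        raise ValueError("background_peaks must be non-empty")
    x = np.array([region_coverage(control_track, p) for p in background_peaks])
    y = np.array([region_coverage(fused_track, p) for p in background_peaks])
    if not x.any():
        raise ValueError("all control coverages are zero over background peaks")
    if fit_intercept:
        slope, _ = np.polyfit(x, y, 1)
        return float(slope)
    return _origin_slope(x, y)


def apply_genotype_scale(fused_track: CoverageTrack, m_prime: float) -> CoverageTrack:
    """Divide a fused track by ``m'`` to put it on the control's depth scale."""
    if m_prime <= 0:
        raise ValueError("m_prime must be > 0")
    out = CoverageTrack(fused_track.chrom_lengths)
    for c in out.chrom_lengths:
        out.data[c] = fused_track.data[c] / m_prime
    return out


def normalize_genotype(
    rep1: CoverageTrack,
    rep2: CoverageTrack,
    control: CoverageTrack,
    peaks: Sequence[GenomicInterval],
    background_peaks: Sequence[GenomicInterval],
    symmetric_fusion: bool = False,
) -> Tuple[CoverageTrack, ScaleFactors]:
    """Run the full two-step normalization for one genotype.

    ``peaks`` are the genotype's bound regions used to fit the replicate
    coefficient ``m`` (callers may pass only the most significant ones);
    ``background_peaks`` are control-called intervals used to fit ``m'``.
    Returns the normalized track and the fitted coefficients.
    """
    pairs = [
        (region_coverage(rep1, p), region_coverage(rep2, p)) for p in peaks
    ]
    m = fit_replicate_scale(pairs)
    fused = fuse_replicates(rep1, rep2, m, symmetric=symmetric_fusion)
    m_prime = fit_genotype_scale(fused, control, background_peaks)
    normalized = apply_genotype_scale(fused, m_prime)

    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    rep_rms = float(np.sqrt(np.mean((y - m * x) ** 2))) if len(pairs) else float("nan")
    cx = np.array([region_coverage(control, p) for p in background_peaks])
    cy = np.array([region_coverage(fused, p) for p in background_peaks])
    bg_rms = float(np.sqrt(np.mean((cy - m_prime * cx) ** 2)))
    factors = ScaleFactors(
        m=m,
        m_prime=m_prime,
        n_replicate_points=len(pairs),
        n_background_peaks=len(background_peaks),
        replicate_residual_rms=rep_rms,
        background_residual_rms=bg_rms,
    )
    return normalized, factors


def compute_cfr(
    regions: Sequence[GenomicInterval],
    ref_track: CoverageTrack,
    alt_track: CoverageTrack,
    cap: float = DEFAULT_CFR_CAP,
    min_alt_coverage: Optional[float] = None,
) -> List[CFRRecord]:
    """Coverage fold reduction per region: normalized reference coverage over
    normalized mutant coverage.

    Regions whose mutant coverage falls below ``min_alt_coverage`` (default:
    the area of one extended read, 130) take ``cfr = cap`` with
    ``capped = True`` — the ratio there is unstable or infinite.  Output order
    matches input order.
    """
    if min_alt_coverage is None:
        min_alt_coverage = float(DEFAULT_FRAGMENT_LENGTH)
    records: List[CFRRecord] = []
    for region in regions:
        cov_ref = region_coverage(ref_track, region)
        cov_alt = region_coverage(alt_track, region)
        if cov_alt < min_alt_coverage:
            records.append(CFRRecord(region, cov_ref, cov_alt, cap, True))
        else:
            records.append(CFRRecord(region, cov_ref, cov_alt, cov_ref / cov_alt, False))
    return records
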