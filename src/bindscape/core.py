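"""Domain types and plain-text genomic I/O.

All intervals are 0-based half-open (native BED/bedGraph convention); conversion,
if ever needed, happens at I/O boundaries only.  Coverage tracks are dense
per-base float arrays keyed by chromosome: raw read counts are integers but
normalization produces non-integer values, so tracks are real-valued throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_CATEGORIES = ("CDS", "intron", "upstream", "downstream", "intergenic")


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph records; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally labelled and ranked."""

    chrom: str
    start: int
    end: int
    id: Optional[str] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class CoverageTrack:
    """Dense per-base non-negative coverage, one float array per chromosome."""

    def __init__(self, chrom_lengths: Mapping[str, int]):
        self.chrom_lengths: Dict[str, int] = dict(chrom_lengths)
        self.data: Dict[str, np.ndarray] = {
            c: np.zeros(n, dtype=np.float64) for c, n in self.chrom_lengths.items()
        }

    def __getitem__(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.data[chrom]

    def copy(self) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_lengths)
        for c in self.data:
            out.data[c] = self.data[c].copy()
        return out

    def same_namespace(self, other: "CoverageTrack") -> bool:
        return self.chrom_lengths == other.chrom_lengths

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))


@dataclass
class GenomeSequence:
    """Upper-case nucleotide sequences ({A,C,G,T,N}) keyed by chromosome."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        self.sequences = {name: s.upper() for name, s in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, region: GenomicInterval) -> str:
        seq = self[region.chrom]
        if region.end > len(seq):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        return seq[region.start : region.end]


@dataclass
class AnnotationCatalog:
    """Genome annotation as interval sets per category.

    ``intergenic`` is the implicit complement: a position falling in no listed
    interval classifies as intergenic, so the catalog always covers the genome.
    """

    categories: Dict[str, List[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in self.categories:
            if cat not in ANNOTATION_CATEGORIES:
                raise ValueError(f"unknown annotation category {cat!r}")

    def classify(self, chrom: str, pos: int) -> str:
        """Category of a single position; first listed category wins."""
        for cat in ANNOTATION_CATEGORIES:
            for iv in self.categories.get(cat, ()):
                if iv.chrom == chrom and iv.start <= pos < iv.end:
                    return cat
        return "intergenic"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path) -> List[GenomicInterval]:
    """Read a 3-5 column BED file into intervals (file order preserved).

    Column 4 maps to ``id`` and column 5 to integer ``rank`` when present.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "" else None
            rank: Optional[int] = None
            if len(fields) > 4 and fields[4] != "":
                try:
                    rank = int(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-integer rank"
                    ) from exc
            try:
                out.append(GenomicInterval(fields[0], start, end, id=name, rank=rank))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as tab-separated BED; columns 4/5 only when set."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.id is not None or iv.rank is not None:
                fields.append(iv.id if iv.id is not None else ".")
            if iv.rank is not None:
                fields.append(str(iv.rank))
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path, chrom_lengths: Mapping[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense track.

    Unspecified positions are zero.  Records past a declared chromosome end,
    on undeclared chromosomes, or overlapping a previous record are errors
    (the pipeline's own bedGraph output is non-overlapping by construction).
    """
    track = CoverageTrack(chrom_lengths)
    covered: Dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=bool) for c, n in track.chrom_lengths.items()
    }
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: expected 4 columns")
            chrom = fields[0]
            if chrom not in track.chrom_lengths:
                raise BedParseError(
                    f"{path}: line {lineno}: undeclared chromosome {chrom!r}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: malformed record") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}: line {lineno}: invalid interval")
            if end > track.chrom_lengths[chrom]:
                raise BedParseError(
                    f"{path}: line {lineno}: record exceeds chromosome length"
                )
            if covered[chrom][start:end].any():
                raise BedParseError(f"{path}: line {lineno}: overlapping records")
            covered[chrom][start:end] = True
            track.data[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as run-length-encoded bedGraph, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            # boundaries of maximal constant runs
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_fasta(path) -> GenomeSequence:
    """Read FASTA; sequences keyed by the first token of each header."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython's writer wraps at its own default; value is cosmetic


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def region_coverage(track: CoverageTrack, region: GenomicInterval) -> float:
    """Coverage of a region: the area above the per-base read-count curve,
    i.e. the sum of track values over [start, end)."""
    arr = track[region.chrom]
    if region.end > arr.size:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds track bounds"
        )
    return float(arr[region.start : region.end].sum())


def intersect_regions(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Members of ``a`` overlapping (>=1 bp) any member of ``b``, order preserved.

    Half-open convention: intervals that merely touch do not overlap.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        starts[chrom] = np.array([x.start for x in ivs])
        ends[chrom] = np.array([x.end for x in ivs])
    out = []
    for iv in a:
        if iv.chrom in starts:
            hit = (starts[iv.chrom] < iv.end) & (ends[iv.chrom] > iv.start)
            if hit.any():
                out.append(iv)
    return out


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals (touching runs fuse)."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged
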