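"""Synthetic ChIP-seq / motif / accessibility fixture generator with known
ground truth.

Every pipeline input is emulated: a random genome, an informative PWM in
max-0 convention, bound regions with planted motif sites, coverage tracks for
two genotypes x two replicates plus a control genotype, and DNase
accessibility files.  The generator plants the statistical structure the
pipeline is meant to detect: the per-region occupancy fold reduction depends
on the region's best site score, its number of 1-bp-spaced site pairs, and
its chromatin state, and the tracks carry known replicate (``m_true``) and
depth (``depth_ref``/``depth_alt``) distortions plus Poisson read noise.

Two site-planting modes exist because two different analyses are exercised:

* ``landscape`` (default) varies the best-score target, extra-site count and
  1-bp-pair count across regions — the substrate for the decile analyses.
* ``window_uniform`` plants, per region and per unit score window above a
  floor, one site with fixed probability — the substrate for recovering the
  affinity threshold, whose per-window median-density rule needs most regions
  to carry a site in every enriched window.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ANNOTATION_CATEGORIES,
    AnnotationCatalog,
    CoverageTrack,
    GenomeSequence,
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_fasta,
)
from .motifs import BASES, PWM, scan_sequence, score_window
from .occupancy import DEFAULT_FRAGMENT_LENGTH


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    The genome mimics a gene-dense plant chromosome arm (2 Mb, GC 0.36); 300
    bound regions and 100 control background peaks keep every analysis
    decile-able while finishing in seconds.  Reference-genotype peaks carry
    200 expected extended reads (well above the 50-read regime where Poisson
    noise still allows ~10-20% recovery error), replicate 2 is scaled by
    ``m_true`` and the genotypes differ from the control's depth by
    ``depth_ref``/``depth_alt``.
    """

    seed: int
    genome_length: int = 2_000_000
    chrom_count: int = 1
    gc: float = 0.36
    n_regions: int = 300
    region_length_range: Tuple[int, int] = (500, 900)
    n_background_peaks: int = 100
    bg_peak_height_range: Tuple[float, float] = (40.0, 100.0)
    bg_peak_width_range: Tuple[int, int] = (200, 500)
    background_level: float = 0.05
    peak_reads_ref: float = 200.0
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    m_true: float = 1.5
    depth_ref: float = 1.2
    depth_alt: float = 0.8
    noise: bool = True
    n_zero_alt: int = 2
    # fold-reduction model: log f = log(f_base) + beta_score * (-best/15)
    #                               + beta_pair * pairs + beta_closed * closed + eps
    f_base: float = 2.0
    beta_score: float = 1.2
    beta_pair: float = 1.25
    beta_closed: float = 1.5
    f_noise_sd: float = 0.3
    f_range: Tuple[float, float] = (1.3, 250.0)
    p_closed: float = 0.35
    # motif planting
    pwm_length: int = 19
    site_mode: str = "landscape"  # landscape | window_uniform | none
    best_score_range: Tuple[float, float] = (-15.0, 0.0)
    extra_sites_mean: float = 3.0
    extra_score_spread: float = 8.0
    pair_probs: Tuple[float, float, float] = (0.70, 0.20, 0.10)
    site_floor: float = -20.0  # window_uniform mode
    window_site_prob: float = 0.7  # window_uniform mode
    # planted-truth cleanup (window_uniform mode): chance motif hits scoring
    # in the band [site_floor - 6, site_floor) are edited out of bound
    # regions, so the windows just below the floor carry no spurious
    # enrichment from planted-site shoulders; hits above the floor are left
    # as shared background.  Override the band's lower edge with scrub_below.
    scrub_chance_sites: bool = True
    scrub_below: Optional[float] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must lie in (0, 1)")
        if self.m_true <= 0 or self.depth_ref <= 0 or self.depth_alt <= 0:
            raise ValueError("scale factors must be positive")
        if self.site_mode not in ("landscape", "window_uniform", "none"):
            raise ValueError(f"unknown site_mode {self.site_mode!r}")


@dataclass
class PlantedSite:
    offset: int  # region-relative
    score: float


@dataclass
class RegionTruth:
    """Ground truth for one bound region."""

    region_id: str
    chrom: str
    start: int
    end: int
    fold_reduction: float  # inf for zero-occupancy mutant regions
    closed: bool
    best_score: float
    unit_gap_pairs: int
    sites: List[PlantedSite] = field(default_factory=list)


@dataclass
class TruthManifest:
    """Everything the recovery tests compare against."""

    m_true: float
    depth_ref: float
    depth_alt: float
    site_mode: str
    site_floor: Optional[float]
    regions: List[RegionTruth] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        for reg in payload["regions"]:
            if reg["fold_reduction"] == float("inf"):
                reg["fold_reduction"] = "inf"
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        regions = []
        for reg in payload.pop("regions"):
            if reg["fold_reduction"] == "inf":
                reg["fold_reduction"] = float("inf")
            sites = [PlantedSite(**s) for s in reg.pop("sites")]
            regions.append(RegionTruth(sites=sites, **reg))
        return cls(regions=regions, **payload)


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def gen_genome(
    length: int, gc: float, seed, chrom_count: int = 1
) -> GenomeSequence:
    """I.i.d. random genome with the requested GC fraction (split evenly
    between G and C); deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    gcp = gc / 2.0
    per = length // chrom_count
    seqs = {}
    for i in range(chrom_count):
        n = per if i < chrom_count - 1 else length - per * (chrom_count - 1)
        draws = rng.choice(4, size=n, p=[at, gcp, gcp, at])
        seqs[f"chr{i + 1}"] = "".join(BASES[b] for b in draws)
    return GenomeSequence(seqs)


def gen_pwm(L: int, seed, consensus_gc: float = 0.5) -> PWM:
    """Random informative PWM: one zero-weight consensus base per position,
    the other bases penalized by 1-4 score units (max-0 convention holds by
    construction; min_score is well below -10 for any L >= 4).

    ``consensus_gc`` biases the consensus base composition so that densely
    planted regions keep a GC content close to the host genome's.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(seed)
    # mismatch penalties of 1.5-5.5 score units give an informative matrix:
    # random genomic background stays sparse (<1 site/kb above -21) while
    # single-substitution steps as small as ~1.5 keep every unit score
    # window constructible for the site planter
    weights = -rng.uniform(1.5, 5.5, size=(L, 4))
    at, gc = (1.0 - consensus_gc) / 2.0, consensus_gc / 2.0
    for j in range(L):
        weights[j, rng.choice(4, p=[at, gc, gc, at])] = 0.0
    return PWM(weights)


def plant_site(
    sequence: list,
    pwm: PWM,
    position: int,
    target_score: float,
    tol: float = 1.0,
    seed=None,
) -> float:
    """Overwrite an L-mer (in a mutable list of bases) with one scoring within
    ``tol`` of ``target_score``; returns the achieved score.

    Greedy descent from the consensus over single and paired base
    substitutions: each step applies the move that brings the score closest to
    the target, stopping when no move improves |score - target|.  Pair moves
    make the achievable score spectrum dense enough to land inside unit score
    windows.
    """
    if target_score < pwm.min_score:
        raise ValueError(f"target {target_score} below PWM minimum {pwm.min_score}")
    if position + pwm.length > len(sequence):
        raise ValueError("site would extend past the end of the chromosome")
    rng = np.random.default_rng(seed)
    L = pwm.length
    W = pwm.weights
    # start from a randomized-tie consensus so repeated plants differ
    cur = (W + rng.uniform(0, 1e-9, size=W.shape)).argmax(axis=1)
    pos_of = np.repeat(np.arange(L), 4)
    base_of = np.tile(np.arange(4), L)
    same_pos = pos_of[:, None] == pos_of[None, :]
    score = float(W[np.arange(L), cur].sum())
    while True:
        err = abs(score - target_score)
        delta = (W - W[np.arange(L), cur][:, None]).ravel()
        single_err = np.abs(score + delta - target_score)
        pair = delta[:, None] + delta[None, :]
        pair_err = np.abs(score + pair - target_score)
        pair_err[same_pos] = np.inf  # two moves at one position collapse to one
        si = int(np.argmin(single_err))
        pi, pj = np.unravel_index(int(np.argmin(pair_err)), pair_err.shape)
        if min(single_err[si], pair_err[pi, pj]) >= err - 1e-12:
            break
        if single_err[si] <= pair_err[pi, pj]:
            cur[pos_of[si]] = base_of[si]
            score += delta[si]
        else:
            cur[pos_of[pi]] = base_of[pi]
            cur[pos_of[pj]] = base_of[pj]
            score += delta[pi] + delta[pj]
    current = [BASES[b] for b in cur]
    achieved = score_window(pwm, "".join(current))
    if abs(achieved - target_score) > tol:
        raise RuntimeError(
            f"could not plant site within {tol} of {target_score} (got {achieved:.2f})"
        )
    sequence[position : position + L] = current
    return achieved


# ---------------------------------------------------------------------------
# Region and site layout
# ---------------------------------------------------------------------------


def _place_intervals(
    rng: np.random.Generator,
    chrom_lengths: Dict[str, int],
    widths: Sequence[int],
    occupied: List[Tuple[str, int, int]],
    margin: int = 300,
    max_tries: int = 200000,
) -> List[Tuple[str, int, int]]:
    """Randomly place non-overlapping intervals (with margin) avoiding
    ``occupied``; appends to and returns the placements."""
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    placed = []
    for width in widths:
        ok = False
        for _ in range(max_tries):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            limit = chrom_lengths[chrom] - width - margin
            if limit <= margin:
                continue
            start = int(rng.integers(margin, limit))
            end = start + width
            clash = any(
                c == chrom and start - margin < e and s < end + margin
                for c, s, e in occupied
            )
            if not clash:
                occupied.append((chrom, start, end))
                placed.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise RuntimeError("could not place all intervals; genome too crowded")
    return placed


def _plan_sites_landscape(
    rng: np.random.Generator, cfg: SimConfig, region_len: int
) -> Tuple[List[float], List[int], int, float]:
    """Site plan for one region in landscape mode.

    Returns (target scores, offsets, unit-gap pair count, best target).
    One site at the region's best-score target, ``pairs`` 1-bp-gap pairs at
    scores at or below the best, and a Poisson number of weaker extras.
    """
    L = cfg.pwm_length
    best = rng.uniform(*cfg.best_score_range)
    n_pairs = int(rng.choice(3, p=cfg.pair_probs))
    n_extra = int(rng.poisson(cfg.extra_sites_mean))
    # groups laid out left to right: the best single site, then 1-bp-gap
    # pairs, then weaker extras; remaining groups are dropped if the region
    # fills up (pairs placed first after the best so they survive truncation)
    groups: List[Tuple[str, float]] = [("single", best)]
    groups += [("pair", best - rng.uniform(0.0, 3.0)) for _ in range(n_pairs)]
    groups += [
        ("single", best - rng.uniform(0.0, cfg.extra_score_spread))
        for _ in range(n_extra)
    ]
    scores: List[float] = []
    offsets: List[int] = []
    achieved_pairs = 0
    pos = int(rng.integers(5, 40))
    for kind, s in groups:
        span = (2 * L + 1) if kind == "pair" else L
        if pos + span > region_len - 5:
            continue
        if kind == "pair":
            offsets += [pos, pos + L + 1]  # footprints separated by a 1-bp gap
            scores += [s, s]
            achieved_pairs += 1
        else:
            offsets.append(pos)
            scores.append(s)
        pos += span + int(rng.integers(4, 60))
    return scores, offsets, achieved_pairs, best


def _plan_sites_window_uniform(
    rng: np.random.Generator, cfg: SimConfig, region_len: int
) -> Tuple[List[float], List[int]]:
    """Site plan in window_uniform mode: one site per unit score window above
    the floor with probability ``window_site_prob``."""
    L = cfg.pwm_length
    n_win = int(np.ceil(-cfg.site_floor))
    scores = []
    for k in range(n_win):
        if rng.random() < cfg.window_site_prob:
            # centred in the window so planting error keeps it in-window;
            # the best window gets the consensus itself (score 0 lies in
            # (-1, 0]; fractional scores above -1 are not constructible)
            scores.append(0.0 if k == 0 else -k - rng.uniform(0.15, 0.85))
    rng.shuffle(scores)
    offsets = []
    pos = int(rng.integers(5, 20))
    kept = []
    for s in scores:
        if pos + L > region_len - 5:
            break
        offsets.append(pos)
        kept.append(s)
        pos += L + int(rng.integers(2, 8))
    return kept, offsets


def _scrub_chance_sites(
    chrom_bases: list,
    pwm: PWM,
    region: GenomicInterval,
    planted_offsets: Sequence[int],
    scrub_floor: float,
    scrub_ceiling: float,
    rng: np.random.Generator,
    max_rounds: int = 12,
) -> None:
    """Edit chance motif hits in a score band out of a bound region.

    Any window (either strand) scoring in [scrub_floor, scrub_ceiling) whose
    offset is not a planted site gets one base outside every planted
    footprint mutated to the least-favourable base for that window; repeated
    until no such hit remains.  Planted footprints are never touched, so
    recorded site scores stay exact, and hits above the ceiling are left as
    shared background.  Windows with no editable base (only the reverse
    strand of a planted footprint itself) are left alone.
    """
    from .motifs import _strand_scores, encode_sequence

    L = pwm.length
    planted = set(planted_offsets)
    fp = np.zeros(len(region), dtype=bool)
    for off in planted:
        fp[off : off + L] = True
    rc = pwm.reverse_complement()
    for _ in range(max_rounds):
        seq = "".join(chrom_bases[region.start : region.end])
        code = encode_sequence(seq)
        fwd = _strand_scores(pwm, code)
        rev = _strand_scores(rc, code)
        # positions covered by any window at or above the ceiling (either
        # strand) are off-limits: editing them could drag supra-ceiling
        # background below the floor and distort the shared background
        protected = fp.copy()
        for arr in (fwd, rev):
            for off in np.flatnonzero(arr >= scrub_ceiling):
                protected[off : off + L] = True
        spurious = []
        for strand, arr in (("+", fwd), ("-", rev)):
            for off in np.flatnonzero((arr >= scrub_floor) & (arr < scrub_ceiling)):
                if off not in planted:
                    spurious.append((int(off), strand))
        if not spurious:
            return
        edited = set()
        for off, strand in spurious:
            editable = [
                p for p in range(off, off + L)
                if not protected[p] and p not in edited
            ]
            if not editable:
                continue
            p = editable[int(rng.integers(0, len(editable)))]
            j = p - off
            matrix = pwm.weights if strand == "+" else rc.weights
            # among near-minimal weights prefer A/T, limiting GC drift of
            # the region relative to the untouched genome
            w = matrix[j]
            near_min = [b for b in range(4) if w[b] <= w.min() + 1.0]
            at_first = [b for b in near_min if BASES[b] in "AT"]
            chrom_bases[region.start + p] = BASES[(at_first or near_min)[0]]
            edited.add(p)
        if not edited:
            return


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------


def _triangular_kernel(length: int, area: float) -> np.ndarray:
    """Symmetric triangular bump of the given area over ``length`` bases."""
    x = np.arange(length, dtype=float)
    mid = (length - 1) / 2.0
    shape = 1.0 - np.abs(x - mid) / (mid + 1.0)
    shape = np.clip(shape, 0.0, None)
    total = shape.sum()
    return shape * (area / total) if total > 0 else shape


def gen_tracks(
    cfg: SimConfig,
    chrom_lengths: Dict[str, int],
    regions: Sequence[GenomicInterval],
    fold_reductions: Sequence[float],
    bg_peaks: Sequence[GenomicInterval],
    bg_heights: Sequence[float],
    rng: np.random.Generator,
) -> Dict[str, CoverageTrack]:
    """Expected-signal construction plus optional Poisson noise for the five
    tracks: ref_rep1/2, alt_rep1/2 and control.

    Expected signal = flat background + shared background-peak kernels +
    genotype-specific bound-region kernels (reference amplitude set by
    ``peak_reads_ref`` expected extended reads; mutant amplitude divided by
    the planted fold reduction).  Replicate 2 is replicate 1's expectation
    times ``m_true``; genotype depths scale everything including background.
    """
    base = {
        c: np.full(n, cfg.background_level, dtype=float)
        for c, n in chrom_lengths.items()
    }
    for peak, h in zip(bg_peaks, bg_heights):
        kern = _triangular_kernel(len(peak), area=h * len(peak) / 2.0)
        base[peak.chrom][peak.start : peak.end] += kern

    ref_sig = {c: a.copy() for c, a in base.items()}
    alt_sig = {c: a.copy() for c, a in base.items()}
    area_ref = cfg.peak_reads_ref * cfg.fragment_length
    for region, f in zip(regions, fold_reductions):
        kern = _triangular_kernel(len(region), area_ref)
        ref_sig[region.chrom][region.start : region.end] += kern
        if np.isfinite(f):
            alt_sig[region.chrom][region.start : region.end] += kern / f

    expectations = {
        "control": base,
        "ref_rep1": {c: cfg.depth_ref * a for c, a in ref_sig.items()},
        "ref_rep2": {c: cfg.depth_ref * cfg.m_true * a for c, a in ref_sig.items()},
        "alt_rep1": {c: cfg.depth_alt * a for c, a in alt_sig.items()},
        "alt_rep2": {c: cfg.depth_alt * cfg.m_true * a for c, a in alt_sig.items()},
    }
    tracks: Dict[str, CoverageTrack] = {}
    for name, exp in expectations.items():
        track = CoverageTrack(chrom_lengths)
        for c in chrom_lengths:
            track.data[c] = (
                rng.poisson(exp[c]).astype(float) if cfg.noise else exp[c].copy()
            )
        tracks[name] = track
    return tracks


def gen_reads(
    track_expectation: CoverageTrack,
    fragment_length: int,
    rng: np.random.Generator,
) -> List:
    """Read-level mode: draw 5' read positions whose extended coverage has
    approximately the given expectation (count = area / fragment length,
    positions sampled proportional to local expected coverage)."""
    from .occupancy import ReadAlignment

    reads = []
    for chrom, exp in track_expectation.data.items():
        total = exp.sum()
        n_reads = rng.poisson(total / fragment_length)
        if n_reads == 0 or total == 0:
            continue
        probs = exp / total
        positions = rng.choice(exp.size, size=n_reads, p=probs)
        strands = rng.choice(list("+-"), size=n_reads)
        for pos, strand in zip(positions, strands):
            # shift so the extended fragment is centred near the sampled base
            if strand == "+":
                pos = max(0, int(pos) - fragment_length // 2)
            else:
                pos = min(exp.size - 1, int(pos) + fragment_length // 2)
            reads.append(ReadAlignment(chrom, int(pos), str(strand)))
    return reads


# ---------------------------------------------------------------------------
# DHS / annotation
# ---------------------------------------------------------------------------


def gen_dhs(
    regions: Sequence[GenomicInterval],
    closed_flags: Sequence[bool],
    chrom_lengths: Dict[str, int],
    rng: np.random.Generator,
) -> Tuple[List[GenomicInterval], CoverageTrack]:
    """Open intervals and a quantitative DHS signal track.

    Open regions receive an interval covering at least their centred half and
    a high per-base signal; closed regions receive either nothing or a
    fragment strictly smaller than the centred half, with low signal.
    """
    open_intervals: List[GenomicInterval] = []
    signal = CoverageTrack(chrom_lengths)
    for region, closed in zip(regions, closed_flags):
        quarter = len(region) // 4
        half_s, half_e = region.start + quarter, region.end - quarter
        if not closed:
            s = half_s - int(rng.integers(0, quarter + 1))
            e = half_e + int(rng.integers(0, quarter + 1))
            s, e = max(s, 0), min(e, chrom_lengths[region.chrom])
            open_intervals.append(GenomicInterval(region.chrom, s, e))
            amp = rng.uniform(5.0, 15.0)
        else:
            if rng.random() < 0.5 and half_e - half_s > 20:
                # sub-centred-half fragment: never covers the full half
                width = int(rng.integers(5, (half_e - half_s) // 2))
                s = int(rng.integers(half_s + 1, half_e - width))
                open_intervals.append(GenomicInterval(region.chrom, s, s + width))
                s, e = s, s + width
            else:
                s, e = half_s, half_e
            amp = rng.uniform(0.1, 1.0)
        signal.data[region.chrom][s:e] += amp
    return open_intervals, signal


def gen_annotation(chrom_lengths: Dict[str, int]) -> AnnotationCatalog:
    """A deterministic toy gene grid: every 5 kb an upstream/CDS/intron/CDS/
    downstream cassette; everything else is implicit intergenic."""
    cats: Dict[str, List[GenomicInterval]] = {c: [] for c in ANNOTATION_CATEGORIES[:4]}
    for chrom, n in chrom_lengths.items():
        for gstart in range(0, n - 3000, 5000):
            cats["upstream"].append(GenomicInterval(chrom, gstart, gstart + 500))
            cats["CDS"].append(GenomicInterval(chrom, gstart + 500, gstart + 1300))
            cats["intron"].append(GenomicInterval(chrom, gstart + 1300, gstart + 1600))
            cats["CDS"].append(GenomicInterval(chrom, gstart + 1600, gstart + 2300))
            cats["downstream"].append(GenomicInterval(chrom, gstart + 2300, gstart + 2800))
    return AnnotationCatalog(categories=cats)


# ---------------------------------------------------------------------------
# Full fixture
# ---------------------------------------------------------------------------


def build_fixture(cfg: SimConfig):
    """Generate every input in memory; returns a dict of objects plus the manifest."""
    rng = np.random.default_rng(cfg.seed)
    genome = gen_genome(cfg.genome_length, cfg.gc, rng.integers(2**31), cfg.chrom_count)
    chrom_lengths = genome.chrom_lengths
    pwm = gen_pwm(cfg.pwm_length, rng.integers(2**31), consensus_gc=cfg.gc)

    occupied: List[Tuple[str, int, int]] = []
    widths = [
        int(rng.integers(cfg.region_length_range[0], cfg.region_length_range[1] + 1))
        for _ in range(cfg.n_regions)
    ]
    placements = _place_intervals(rng, chrom_lengths, widths, occupied)
    regions = [
        GenomicInterval(c, s, e, id=f"region_{i:04d}", rank=i + 1)
        for i, (c, s, e) in enumerate(placements)
    ]
    bg_widths = [
        int(rng.integers(cfg.bg_peak_width_range[0], cfg.bg_peak_width_range[1] + 1))
        for _ in range(cfg.n_background_peaks)
    ]
    bg_placements = _place_intervals(rng, chrom_lengths, bg_widths, occupied)
    bg_peaks = [
        GenomicInterval(c, s, e, id=f"bgpeak_{i:03d}")
        for i, (c, s, e) in enumerate(bg_placements)
    ]
    bg_heights = [
        float(rng.uniform(*cfg.bg_peak_height_range)) for _ in bg_peaks
    ]

    # mutable per-chromosome base lists for site planting
    mutable = {c: list(s) for c, s in genome.sequences.items()}
    manifest = TruthManifest(
        m_true=cfg.m_true,
        depth_ref=cfg.depth_ref,
        depth_alt=cfg.depth_alt,
        site_mode=cfg.site_mode,
        site_floor=cfg.site_floor if cfg.site_mode == "window_uniform" else None,
    )
    closed_flags = rng.random(cfg.n_regions) < cfg.p_closed
    zero_alt_idx = set(
        rng.choice(cfg.n_regions, size=cfg.n_zero_alt, replace=False).tolist()
    ) if cfg.n_zero_alt else set()

    fold_reductions: List[float] = []
    for i, region in enumerate(regions):
        closed = bool(closed_flags[i])
        if cfg.site_mode == "landscape":
            scores, offsets, pairs, best = _plan_sites_landscape(rng, cfg, len(region))
        elif cfg.site_mode == "window_uniform":
            scores, offsets = _plan_sites_window_uniform(rng, cfg, len(region))
            pairs, best = 0, (max(scores) if scores else cfg.site_floor)
        else:
            scores, offsets, pairs, best = [], [], 0, 0.0
        planted: List[PlantedSite] = []
        for target, off in zip(scores, offsets):
            achieved = plant_site(
                mutable[region.chrom],
                pwm,
                region.start + off,
                target,
                tol=1.0,
                seed=rng.integers(2**31),
            )
            planted.append(PlantedSite(offset=off, score=float(achieved)))
        if planted:
            best = max(s.score for s in planted)  # truth records achieved scores
        if planted and cfg.scrub_chance_sites and (
            cfg.site_mode == "window_uniform" or cfg.scrub_below is not None
        ):
            scrub_floor = (
                cfg.scrub_below if cfg.scrub_below is not None
                else cfg.site_floor - 6.0
            )
            scrub_floor = max(scrub_floor, pwm.min_score + 1.0)
            _scrub_chance_sites(
                mutable[region.chrom], pwm, region, [s.offset for s in planted],
                scrub_floor, cfg.site_floor, rng,
            )
        if i in zero_alt_idx:
            f = float("inf")
        else:
            logf = (
                np.log(cfg.f_base)
                + cfg.beta_score * (-best / 15.0)
                + cfg.beta_pair * pairs
                + cfg.beta_closed * closed
                + rng.normal(0.0, cfg.f_noise_sd)
            )
            f = float(np.clip(np.exp(logf), cfg.f_range[0], cfg.f_range[1]))
        fold_reductions.append(f)
        manifest.regions.append(
            RegionTruth(
                region_id=region.id,
                chrom=region.chrom,
                start=region.start,
                end=region.end,
                fold_reduction=f,
                closed=closed,
                best_score=float(best),
                unit_gap_pairs=pairs,
                sites=planted,
            )
        )
    genome = GenomeSequence({c: "".join(b) for c, b in mutable.items()})

    tracks = gen_tracks(
        cfg, chrom_lengths, regions, fold_reductions, bg_peaks, bg_heights, rng
    )
    open_intervals, dhs_signal = gen_dhs(regions, closed_flags, chrom_lengths, rng)
    annotation = gen_annotation(chrom_lengths)
    return {
        "genome": genome,
        "pwm": pwm,
        "regions": regions,
        "bg_peaks": bg_peaks,
        "tracks": tracks,
        "open_intervals": open_intervals,
        "dhs_signal": dhs_signal,
        "annotation": annotation,
        "manifest": manifest,
    }


def gen_fixture(cfg: SimConfig, outdir) -> TruthManifest:
    """Write a complete, pipeline-ready input directory; returns the manifest.

    Emits genome FASTA, PWM TSV, regions BED, five bedGraph tracks, per-
    category annotation BEDs, DHS open-interval BED + signal bedGraph, a
    chromosome-sizes table and the ground-truth manifest JSON.  Byte-identical
    for identical config (seed included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(cfg)
    write_fasta(fx["genome"], outdir / "genome.fa")
    fx["pwm"].to_tsv(outdir / "pwm.tsv")
    write_bed(fx["regions"], outdir / "regions.bed")
    write_bed(fx["bg_peaks"], outdir / "background_peaks_true.bed")
    for name, track in fx["tracks"].items():
        write_bedgraph(track, outdir / f"{name}.bedgraph")
    write_bed(fx["open_intervals"], outdir / "dhs_open.bed")
    write_bedgraph(fx["dhs_signal"], outdir / "dhs_signal.bedgraph")
    for cat, ivs in fx["annotation"].categories.items():
        write_bed(ivs, outdir / f"annotation_{cat}.bed")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for c, n in fx["genome"].chrom_lengths.items():
            fh.write(f"{c}\t{n}\n")
    fx["manifest"].to_json(outdir / "manifest.json")
    return fx["manifest"]
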