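"""PWM scoring of fixed-length windows, GC-matched negative sets, data-driven
affinity-threshold determination, and binding-site spacing analyses.

Scores follow the max-0 convention: the weight matrix has per-position maximum
0, so the optimal L-mer scores 0 and every other window scores negative, down
to ``min_score`` (the sum of per-position minima).  The affinity threshold is
not an arbitrary cutoff: per-region site densities in unit score windows
([0;-1], [-1;-2], ...) are compared between bound regions and a GC- and
length-matched random negative set with a one-sided Mann-Whitney test, and the
threshold is the deep edge of the contiguous significant run that starts at
the best window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationCatalog, GenomeSequence, GenomicInterval

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3; any other letter (N) as 4."""
    table = np.full(128, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return table[arr]


@dataclass
class PWM:
    """An L x 4 additive scoring matrix in max-0 convention (columns A,C,G,T)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("PWM weights must be an L x 4 matrix")
        if not np.allclose(self.weights.max(axis=1), 0.0, atol=1e-9):
            raise ValueError("PWM not in max-0 convention (per-position max != 0)")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.weights[::-1, _COMPLEMENT_IDX])

    @classmethod
    def normalize(cls, raw: np.ndarray) -> "PWM":
        """Rescale an arbitrary additive matrix into max-0 convention by
        subtracting each position's maximum."""
        raw = np.asarray(raw, dtype=float)
        return cls(raw - raw.max(axis=1, keepdims=True))

    @classmethod
    def from_tsv(cls, path) -> "PWM":
        df = pd.read_csv(path, sep="\t")
        missing = [b for b in BASES if b not in df.columns]
        if missing:
            raise ValueError(f"PWM file {path} lacks columns {missing}")
        return cls(df[list(BASES)].to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.weights, columns=list(BASES)).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


@dataclass(frozen=True)
class BindingSite:
    """A scored, stranded motif occurrence within a scanned sequence."""

    region_id: Optional[str]
    offset: int  # 0-based start within the scanned sequence
    strand: str  # '+' or '-'
    score: float


def score_window(pwm: PWM, seq: str) -> float:
    """Score one L-mer: the sum of per-position weights.

    Windows containing N (or any non-ACGT letter) score -inf and are skipped
    by the scanner.
    """
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != PWM length {pwm.length}")
    code = encode_sequence(seq)
    if (code > 3).any():
        return float("-inf")
    return float(pwm.weights[np.arange(pwm.length), code].sum())


def _strand_scores(pwm: PWM, code: np.ndarray) -> np.ndarray:
    """Scores of all windows of one encoded sequence on the + strand; windows
    containing N are -inf."""
    n, L = code.size, pwm.length
    n_win = n - L + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(code > 3, 0, code)
    bad = code > 3
    for j in range(L):
        scores += pwm.weights[j, safe[j : j + n_win]]
        valid &= ~bad[j : j + n_win]
    scores[~valid] = float("-inf")
    return scores


def scan_sequence(
    pwm: PWM,
    sequence: str,
    threshold: float,
    region_id: Optional[str] = None,
    collapse_strands: bool = True,
) -> List[BindingSite]:
    """All binding sites with score >= threshold, sorted by offset.

    Every offset is scored on the + strand and on the reverse complement; with
    ``collapse_strands`` (default) only the better-scoring strand is reported
    per offset (ties go to +), which avoids double-counting palindromic hits.
    """
    if len(sequence) < pwm.length:
        raise ValueError("sequence shorter than PWM length")
    code = encode_sequence(sequence)
    fwd = _strand_scores(pwm, code)
    rev = _strand_scores(pwm.reverse_complement(), code)
    sites: List[BindingSite] = []
    for off in range(fwd.size):
        f, r = fwd[off], rev[off]
        if collapse_strands:
            # ties (palindromes) go to +; tolerance absorbs summation-order noise
            score, strand = (f, "+") if f >= r - 1e-9 else (r, "-")
            if score >= threshold:
                sites.append(BindingSite(region_id, off, strand, float(score)))
        else:
            if f >= threshold:
                sites.append(BindingSite(region_id, off, "+", float(f)))
            if r >= threshold:
                sites.append(BindingSite(region_id, off, "-", float(r)))
    return sites


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (length - #N); all-N or empty input is an error."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_count = s.count("N")
    denom = len(s) - n_count
    if denom == 0:
        raise ValueError("sequence contains only N")
    return (s.count("G") + s.count("C")) / denom


def sample_negative_set(
    bound_regions: Sequence[GenomicInterval],
    genome: GenomeSequence,
    annotation: Optional[AnnotationCatalog] = None,
    gc_tol: float = 0.05,
    seed: int = 0,
    max_tries: int = 10000,
) -> Tuple[List[GenomicInterval], List[str]]:
    """One random unbound region per bound region, matched in length and GC.

    Candidates are drawn uniformly over the genome (chromosomes weighted by
    length), accepted when |GC_candidate - GC_bound| <= gc_tol and the
    candidate overlaps no bound region.  The annotation category of each
    accepted candidate (by midpoint) is recorded but not constrained.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    negatives: List[GenomicInterval] = []
    categories: List[str] = []
    for i, region in enumerate(bound_regions):
        size = len(region)
        target_gc = gc_content(genome.fetch(region))
        found = False
        for _ in range(max_tries):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            limit = len(genome.sequences[chrom]) - size
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            cand = GenomicInterval(chrom, start, start + size, id=f"neg_{i}")
            if any(cand.overlaps(b) for b in bound_regions):
                continue
            try:
                cand_gc = gc_content(genome.fetch(cand))
            except ValueError:
                continue
            if abs(cand_gc - target_gc) <= gc_tol:
                negatives.append(cand)
                mid = (cand.start + cand.end) // 2
                categories.append(
                    annotation.classify(chrom, mid) if annotation else "intergenic"
                )
                found = True
                break
        if not found:
            raise RuntimeError(
                f"no GC-matched candidate found for region "
                f"{region.chrom}:{region.start}-{region.end} "
                f"(GC {target_gc:.3f}) within {max_tries} tries"
            )
    return negatives, categories


# ---------------------------------------------------------------------------
# Score-window densities and threshold determination
# ---------------------------------------------------------------------------


def n_score_windows(pwm: PWM) -> int:
    """Number of unit score windows [0;-1] .. [min+1; min]."""
    return int(np.ceil(-pwm.min_score))


def window_densities(
    regions: Sequence[GenomicInterval],
    genome: GenomeSequence,
    pwm: PWM,
) -> pd.DataFrame:
    """Per-region site density (sites per kb) in each unit score window.

    Window k (k = 0, 1, ...) covers scores in (-(k+1), -k]; the best window
    [0;-1] holds scores in (-1, 0].  Rows are regions (indexed by id or
    coordinate string), columns are window indices.
    """
    n_win = n_score_windows(pwm)
    rows = []
    index = []
    for region in regions:
        seq = genome.fetch(region)
        sites = scan_sequence(pwm, seq, threshold=pwm.min_score)
        counts = np.zeros(n_win)
        for s in sites:
            # window k covers scores in (-(k+1), -k]; score 0 lands in window 0
            k = int(np.floor(-s.score))
            k = min(max(k, 0), n_win - 1)
            counts[k] += 1
        rows.append(counts * 1000.0 / len(region))
        index.append(region.id or f"{region.chrom}:{region.start}-{region.end}")
    return pd.DataFrame(rows, index=index, columns=range(n_win))


@dataclass
class ThresholdResult:
    """Outcome of the data-driven score-threshold determination."""

    threshold: Optional[int]  # lower bound of the last significant window; None if none
    table: pd.DataFrame = field(repr=False)  # per-window statistics

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def determine_threshold(
    pos_densities: pd.DataFrame,
    neg_densities: pd.DataFrame,
    alpha: float = 0.05,
) -> ThresholdResult:
    """Affinity threshold from per-window density comparisons.

    For each unit score window, per-region densities of the positive (bound)
    set are compared with the negative set by a one-sided Mann-Whitney test
    (positive > negative).  A window is significant when p < alpha and the
    positive median density exceeds the negative median.  The threshold is the
    lower bound of the deepest window in the maximal contiguous significant
    run starting at the best window [0;-1]; with no significant first window
    the threshold is None.
    """
    if not pos_densities.columns.equals(neg_densities.columns):
        raise ValueError("positive and negative density tables have different window grids")
    if len(pos_densities) < 2 or len(neg_densities) < 2:
        raise ValueError("need >= 2 regions per set")
    records = []
    for k in pos_densities.columns:
        x = pos_densities[k].to_numpy()
        y = neg_densities[k].to_numpy()
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0  # both sets constant and equal: no evidence either way
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)
        sig = p < alpha and float(np.median(x)) > float(np.median(y))
        records.append(
            {
                "window_hi": -int(k),
                "window_lo": -(int(k) + 1),
                "pos_median": float(np.median(x)),
                "neg_median": float(np.median(y)),
                "p_value": p,
                "significant": bool(sig),
            }
        )
    table = pd.DataFrame(records)
    threshold: Optional[int] = None
    for rec in records:
        if rec["significant"]:
            threshold = rec["window_lo"]
        else:
            break
    return ThresholdResult(threshold=threshold, table=table)


# ---------------------------------------------------------------------------
# Per-region landscape statistics
# ---------------------------------------------------------------------------


def region_best_score(region: GenomicInterval, genome: GenomeSequence, pwm: PWM) -> float:
    """Maximum site score over both strands within the region."""
    if len(region) < pwm.length:
        raise ValueError("region shorter than PWM length")
    seq = genome.fetch(region)
    code = encode_sequence(seq)
    fwd = _strand_scores(pwm, code)
    rev = _strand_scores(pwm.reverse_complement(), code)
    best = max(fwd.max(), rev.max())
    if best == float("-inf"):
        raise ValueError("region contains no N-free window")
    return float(best)


def region_site_density(
    region: GenomicInterval, genome: GenomeSequence, pwm: PWM, threshold: float
) -> float:
    """Count of supra-threshold sites per kb of region."""
    sites = scan_sequence(pwm, genome.fetch(region), threshold, region_id=region.id)
    return len(sites) * 1000.0 / len(region)


def pairwise_site_distances(sites: Sequence[BindingSite], motif_length: int) -> List[int]:
    """Gap (bp) between the footprints of every unordered pair of sites.

    distance = start_downstream - (start_upstream + L): 1 means a single
    spacer base between the two L-bp footprints, 0 means adjacency; negative
    values (overlapping footprints) are reported as-is.
    """
    offsets = sorted(s.offset for s in sites)
    out: List[int] = []
    for i in range(len(offsets)):
        for j in range(i + 1, len(offsets)):
            out.append(offsets[j] - (offsets[i] + motif_length))
    return out


def count_unit_gap_pairs(sites: Sequence[BindingSite], motif_length: int) -> int:
    """Number of unordered site pairs separated by exactly a 1-bp gap —
    the spacing that most favours tetramer formation."""
    return sum(1 for d in pairwise_site_distances(sites, motif_length) if d == 1)


def spacing_by_decile(
    cfr_records,
    site_map: Dict[str, Sequence[BindingSite]],
    motif_length: int,
    max_distance: int = 40,
    include_overlapping: bool = False,
) -> pd.DataFrame:
    """Histogram of pairwise site gaps per CFR decile.

    Regions are ranked by CFR and split into 10 near-equal groups (decile 0 =
    lowest CFR); for each group all pairwise gaps in [0, max_distance) are
    counted.  Overlapping pairs (negative gap) are excluded by default.
    Returns a 10 x max_distance count matrix (rows deciles, columns gaps).
    """
    from .stats import decile_partition

    partition = decile_partition(cfr_records, key=lambda r: r.cfr)
    matrix = np.zeros((10, max_distance), dtype=int)
    for d, group in enumerate(partition.groups):
        for rec in group:
            rid = rec.region.id or (
                f"{rec.region.chrom}:{rec.region.start}-{rec.region.end}"
            )
            dists = pairwise_site_distances(site_map.get(rid, ()), motif_length)
            for dist in dists:
                if dist < 0 and not include_overlapping:
                    continue
                if 0 <= dist < max_distance:
                    matrix[d, dist] += 1
    return pd.DataFrame(matrix, index=range(10), columns=range(max_distance))
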