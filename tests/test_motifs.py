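"""PWM scoring, scanning, negative sets, threshold determination and spacing."""

import numpy as np
import pandas as pd
import pytest

from bindscape import (
    GenomicInterval,
    PWM,
    count_unit_gap_pairs,
    determine_threshold,
    gc_content,
    pairwise_site_distances,
    region_best_score,
    region_site_density,
    sample_negative_set,
    scan_sequence,
    score_window,
    spacing_by_decile,
    window_densities,
)
from bindscape.core import GenomeSequence
from bindscape.motifs import BindingSite, n_score_windows
from bindscape.occupancy import CFRRecord
from bindscape.simulate import gen_genome, gen_pwm

BASES = "ACGT"


def brute_score(pwm, seq):
    """Independent per-position sum."""
    total = 0.0
    for j, ch in enumerate(seq):
        if ch not in BASES:
            return float("-inf")
        total += pwm.weights[j, BASES.index(ch)]
    return total


def revcomp(seq):
    return seq[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestScoreWindow:
    def test_consensus_scores_zero(self, toy_pwm):
        assert score_window(toy_pwm, toy_pwm.consensus) == 0.0

    def test_worst_sequence_scores_min(self, toy_pwm):
        worst = "".join(BASES[i] for i in toy_pwm.weights.argmin(axis=1))
        assert score_window(toy_pwm, worst) == pytest.approx(toy_pwm.min_score)
        assert toy_pwm.min_score == -28.0

    def test_wrong_length_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            score_window(toy_pwm, "ACGTA")

    def test_n_gives_minus_inf(self, toy_pwm):
        assert score_window(toy_pwm, "ANGT") == float("-inf")

    def test_random_19mers_match_hand_oracle(self, rng):
        pwm = gen_pwm(19, 5)
        for _ in range(50):
            seq = "".join(rng.choice(list(BASES), 19))
            assert score_window(pwm, seq) == pytest.approx(brute_score(pwm, seq))


class TestScanSequence:
    def test_planted_consensus_found(self, toy_pwm, rng):
        seq = "TTTTT" + toy_pwm.consensus + "TTTTT"
        sites = scan_sequence(toy_pwm, seq, threshold=0.0)
        assert [(s.offset, s.score) for s in sites if s.strand == "+"] == [(5, 0.0)]

    def test_threshold_zero_only_exact_matches(self, rng):
        pwm = gen_pwm(8, 7)
        seq = "".join(rng.choice(list(BASES), 500))
        for s in scan_sequence(pwm, seq, threshold=0.0):
            assert s.score == 0.0

    def test_full_enumeration_matches_brute_force(self, rng):
        pwm = gen_pwm(19, 9)
        seq = "".join(rng.choice(list(BASES), 2000))
        sites = scan_sequence(pwm, seq, threshold=pwm.min_score)
        assert len(sites) == len(seq) - 19 + 1
        for s in sites:
            window = seq[s.offset : s.offset + 19]
            f = brute_score(pwm, window)
            r = brute_score(pwm, revcomp(window))
            assert s.score == pytest.approx(max(f, r))
            assert s.strand == ("+" if f >= r - 1e-9 else "-")

    def test_both_strands_reported_when_not_collapsed(self, toy_pwm):
        seq = "AA" + revcomp(toy_pwm.consensus) + "AA"
        sites = scan_sequence(toy_pwm, seq, threshold=0.0, collapse_strands=False)
        assert any(s.strand == "-" and s.score == 0.0 for s in sites)

    def test_strand_symmetry(self, rng):
        pwm = gen_pwm(11, 13)
        seq = "".join(rng.choice(list(BASES), 400))
        fwd = scan_sequence(pwm, seq, threshold=-30)
        rev = scan_sequence(pwm, revcomp(seq), threshold=-30)
        mirrored = sorted((len(seq) - 11 - s.offset, round(s.score, 6)) for s in rev)
        assert sorted((s.offset, round(s.score, 6)) for s in fwd) == mirrored

    def test_scores_within_bounds(self, rng):
        pwm = gen_pwm(9, 21)
        seq = "".join(rng.choice(list(BASES), 300))
        for s in scan_sequence(pwm, seq, threshold=pwm.min_score):
            assert pwm.min_score - 1e-9 <= s.score <= 1e-9


class TestPWMFormat:
    def test_normalize_arbitrary_matrix(self, rng):
        raw = rng.normal(0, 2, size=(6, 4))
        pwm = PWM.normalize(raw)
        np.testing.assert_allclose(pwm.weights.max(axis=1), 0.0, atol=1e-12)

    def test_tsv_round_trip(self, tmp_path):
        pwm = gen_pwm(19, 3)
        p = tmp_path / "pwm.tsv"
        pwm.to_tsv(p)
        back = PWM.from_tsv(p)
        np.testing.assert_allclose(back.weights, pwm.weights, rtol=1e-9)

    def test_non_max0_matrix_rejected(self):
        with pytest.raises(ValueError):
            PWM(np.array([[1.0, 0.0, -1.0, -2.0]]))


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("AATT", 0.0), ("ACGT", 0.5), ("ACGN", 2 / 3)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNN")


@pytest.fixture(scope="module")
def negset_genome():
    return gen_genome(150_000, 0.40, 2024)


class TestNegativeSet:
    def test_contract_and_determinism(self, negset_genome):
        genome = negset_genome
        bound = [GenomicInterval("chr1", 5000 + i * 2000, 5300 + i * 2000, id=f"b{i}")
                 for i in range(30)]
        negs1, cats1 = sample_negative_set(bound, genome, gc_tol=0.05, seed=9)
        negs2, _ = sample_negative_set(bound, genome, gc_tol=0.05, seed=9)
        assert negs1 == negs2
        assert len(negs1) == len(bound)
        deltas = []
        for b, n in zip(bound, negs1):
            assert len(n) == len(b)
            assert not any(n.overlaps(x) for x in bound)
            deltas.append(abs(gc_content(genome.fetch(n)) - gc_content(genome.fetch(b))))
        assert max(deltas) <= 0.05
        assert np.mean(deltas) <= 0.05
        assert all(c in {"CDS", "intron", "upstream", "downstream", "intergenic"}
                   for c in cats1)

    def test_impossible_match_raises(self):
        genome = GenomeSequence({"chr1": "A" * 5000 + "GCGC" * 100 + "A" * 5000})
        bound = [GenomicInterval("chr1", 5000, 5400, id="gc_island")]
        with pytest.raises(RuntimeError, match="gc_island|no GC-matched"):
            sample_negative_set(bound, genome, gc_tol=0.01, seed=1, max_tries=300)


class TestWindowDensities:
    def test_partition_sums_to_total_sites(self, rng):
        pwm = gen_pwm(13, 31)
        genome = gen_genome(30_000, 0.4, 8)
        regions = [GenomicInterval("chr1", i * 3000, i * 3000 + 800, id=f"r{i}")
                   for i in range(8)]
        dens = window_densities(regions, genome, pwm)
        assert dens.shape == (8, n_score_windows(pwm))
        for region in regions:
            sites = scan_sequence(pwm, genome.fetch(region), pwm.min_score)
            row = dens.loc[region.id]
            assert row.sum() * len(region) / 1000.0 == pytest.approx(len(sites))

    def test_counts_match_scan_filter(self, rng):
        pwm = gen_pwm(9, 17)
        genome = gen_genome(5_000, 0.45, 77)
        region = GenomicInterval("chr1", 100, 1100, id="r0")
        dens = window_densities([region], genome, pwm)
        sites = scan_sequence(pwm, genome.fetch(region), pwm.min_score)
        for k in dens.columns:
            brute = sum(1 for s in sites if -(k + 1) < s.score <= -k)
            assert dens.loc["r0", k] * len(region) / 1000.0 == pytest.approx(brute)


class TestDetermineThreshold:
    def _grids(self, n_windows, n_regions=40):
        cols = list(range(n_windows))
        zeros = pd.DataFrame(0.0, index=range(n_regions), columns=cols)
        return zeros.copy(), zeros.copy()

    def test_constructed_run_down_to_minus_25(self):
        pos, neg = self._grids(56)
        for k in range(25):  # windows [0;-1] .. [-24;-25] enriched
            pos[k] = 2.0
        res = determine_threshold(pos, neg)
        assert res.threshold == -25

    def test_equal_densities_give_none(self):
        pos, neg = self._grids(30)
        assert determine_threshold(pos, neg).threshold is None

    def test_gap_in_run_stops_threshold(self):
        pos, neg = self._grids(30)
        for k in [0, 1, 2, 5, 6]:  # hole at window 3 stops the run at -3
            pos[k] = 2.0
        assert determine_threshold(pos, neg).threshold == -3

    def test_grid_mismatch_rejected(self):
        pos, _ = self._grids(20)
        _, neg = self._grids(21)
        with pytest.raises(ValueError):
            determine_threshold(pos, neg)


class TestSpacing:
    def _sites(self, offsets, L=19):
        return [BindingSite("r", off, "+", -1.0) for off in offsets]

    def test_unit_gap_convention(self):
        assert pairwise_site_distances(self._sites([0, 20]), 19) == [1]

    def test_adjacency_is_zero_gap(self):
        assert pairwise_site_distances(self._sites([0, 19]), 19) == [0]

    def test_all_pairs_match_brute_force(self, rng):
        offsets = sorted(int(x) for x in rng.choice(500, size=8, replace=False))
        got = sorted(pairwise_site_distances(self._sites(offsets), 19))
        brute = sorted(
            offsets[j] - offsets[i] - 19
            for i in range(8)
            for j in range(i + 1, 8)
        )
        assert got == brute

    def test_unit_gap_pair_counting(self):
        assert count_unit_gap_pairs([], 19) == 0
        assert count_unit_gap_pairs(self._sites([0, 20]), 19) == 1
        assert count_unit_gap_pairs(self._sites([0, 20, 40]), 19) == 2

    def _records(self, n=20):
        return [
            CFRRecord(GenomicInterval("chr1", i * 100, i * 100 + 90, id=f"r{i}"),
                      cov_ref=10.0, cov_alt=1.0, cfr=float(i + 1), capped=False)
            for i in range(n)
        ]

    def test_single_site_regions_give_zero_matrix(self):
        records = self._records()
        site_map = {f"r{i}": self._sites([5]) for i in range(20)}
        mat = spacing_by_decile(records, site_map, 19)
        assert mat.to_numpy().sum() == 0

    def test_grand_total_conserved(self, rng):
        records = self._records()
        site_map = {}
        total = 0
        for i in range(20):
            offsets = sorted(int(x) for x in rng.choice(60, size=3, replace=False))
            site_map[f"r{i}"] = self._sites(offsets)
            total += sum(
                1 for d in pairwise_site_distances(site_map[f"r{i}"], 19)
                if 0 <= d < 40
            )
        mat = spacing_by_decile(records, site_map, 19, max_distance=40)
        assert mat.to_numpy().sum() == total

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            spacing_by_decile(self._records(5), {}, 19)


class TestRegionStatistics:
    def test_best_score_and_density(self, toy_pwm):
        genome = GenomeSequence({"chr1": "TT" + toy_pwm.consensus + "TTTTTTTTTT"})
        region = GenomicInterval("chr1", 0, len(genome["chr1"]), id="r")
        assert region_best_score(region, genome, toy_pwm) == 0.0
        sites = scan_sequence(toy_pwm, genome.fetch(region), toy_pwm.min_score)
        best = max(s.score for s in sites)
        assert best == region_best_score(region, genome, toy_pwm)
        n_supra = sum(1 for s in sites if s.score >= -5)
        assert region_site_density(region, genome, toy_pwm, -5) == pytest.approx(
            n_supra * 1000.0 / len(region)
        )

    def test_region_shorter_than_motif_rejected(self, toy_pwm):
        genome = GenomeSequence({"chr1": "ACGTACGT"})
        with pytest.raises(ValueError):
            region_best_score(GenomicInterval("chr1", 0, 3), genome, toy_pwm)
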