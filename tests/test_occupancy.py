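"""Extended-read coverage, the two-step normalization and the CFR statistic."""

import numpy as np
import pytest

from bindscape import (
    CoverageTrack,
    GenomicInterval,
    ReadAlignment,
    apply_genotype_scale,
    compute_cfr,
    extend_reads,
    fit_genotype_scale,
    fit_replicate_scale,
    fuse_replicates,
    normalize_genotype,
    rudimentary_peak_find,
)
from bindscape.occupancy import read_reads_bed


def brute_force_extend(reads, chrom_lengths, L):
    """Per-base increment oracle for read extension."""
    arrays = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for r in reads:
        if r.strand == "+":
            span = range(r.pos, min(r.pos + L, chrom_lengths[r.chrom]))
        else:
            span = range(max(r.pos - L + 1, 0), r.pos + 1)
        for p in span:
            arrays[r.chrom][p] += 1
    return arrays


class TestExtendReads:
    def test_plus_read_covers_fragment(self):
        track = extend_reads([ReadAlignment("chr1", 100, "+")], {"chr1": 400})
        arr = track["chr1"]
        assert arr[100:230].sum() == 130 and arr.sum() == 130

    def test_minus_read_covers_upstream(self):
        track = extend_reads([ReadAlignment("chr1", 500, "-")], {"chr1": 600})
        arr = track["chr1"]
        assert (arr[371:501] == 1).all() and arr.sum() == 130

    def test_two_identical_reads_additive(self):
        reads = [ReadAlignment("chr1", 50, "+")] * 2
        track = extend_reads(reads, {"chr1": 300})
        assert (track["chr1"][50:180] == 2).all()

    def test_read_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            extend_reads([ReadAlignment("chr1", 500, "+")], {"chr1": 400})

    def test_matches_brute_force_and_conserves_mass(self, rng):
        chrom_lengths = {"chr1": 700, "chr2": 300}
        reads = [
            ReadAlignment(
                str(rng.choice(["chr1", "chr2"])),
                int(rng.integers(0, 295)),
                str(rng.choice(["+", "-"])),
            )
            for _ in range(200)
        ]
        track = extend_reads(reads, chrom_lengths, fragment_length=130)
        oracle = brute_force_extend(reads, chrom_lengths, 130)
        for c in chrom_lengths:
            np.testing.assert_array_equal(track[c], oracle[c])
        # mass: each read contributes its (possibly edge-truncated) span
        expected = sum(
            min(r.pos + 130, chrom_lengths[r.chrom]) - r.pos
            if r.strand == "+"
            else r.pos + 1 - max(r.pos - 129, 0)
            for r in reads
        )
        assert track.total() == expected

    def test_reads_bed6_parsing(self, tmp_path):
        p = tmp_path / "reads.bed"
        p.write_text("chr1\t10\t50\tr1\t0\t+\nchr1\t60\t100\tr2\t0\t-\n")
        reads = read_reads_bed(p, {"chr1": 200})
        assert reads[0] == ReadAlignment("chr1", 10, "+")
        assert reads[1] == ReadAlignment("chr1", 99, "-")


class TestRudimentaryPeakFinder:
    def test_single_plateau(self):
        track = CoverageTrack({"chr1": 100})
        track.data["chr1"][40:60] = 25.0
        (peak,) = rudimentary_peak_find(track, cutoff=20)
        assert (peak.start, peak.end) == (40, 60)

    def test_all_below_cutoff(self):
        track = CoverageTrack({"chr1": 100})
        track.data["chr1"][:] = 5.0
        assert rudimentary_peak_find(track, cutoff=20) == []

    def test_min_gap_merging(self):
        track = CoverageTrack({"chr1": 100})
        track.data["chr1"][10:20] = 30.0
        track.data["chr1"][25:35] = 30.0
        assert len(rudimentary_peak_find(track, cutoff=20, min_gap=0)) == 2
        merged = rudimentary_peak_find(track, cutoff=20, min_gap=10)
        assert [(p.start, p.end) for p in merged] == [(10, 35)]

    def test_matches_run_enumeration_oracle(self, rng):
        track = CoverageTrack({"chr1": 400})
        track.data["chr1"][:] = rng.choice([0, 10, 25, 40], size=400)
        got = [(p.start, p.end) for p in rudimentary_peak_find(track, cutoff=20)]
        runs, start = [], None
        for i, v in enumerate(track["chr1"]):
            if v >= 20 and start is None:
                start = i
            elif v < 20 and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, 400))
        assert got == runs


class TestScaleFits:
    def test_exact_doubling(self):
        pairs = [(c, 2 * c) for c in range(1, 11)]
        assert fit_replicate_scale(pairs) == pytest.approx(2.0)

    def test_identity(self):
        pairs = [(c, c) for c in range(1, 11)]
        assert fit_replicate_scale(pairs) == pytest.approx(1.0)

    def test_recovery_with_multiplicative_noise(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(50, 500, 200)
        y = 1.5 * x * rng.lognormal(0, 0.05, 200)
        m = fit_replicate_scale(list(zip(x, y)))
        assert 1.4 <= m <= 1.6

    def test_all_zero_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_replicate_scale([(0.0, 1.0), (0.0, 2.0)])

    def test_genotype_scale_exact_and_noisy(self, rng):
        control = CoverageTrack({"chr1": 10000})
        control.data["chr1"][:] = rng.uniform(10, 30, 10000)
        fused = CoverageTrack({"chr1": 10000})
        fused.data["chr1"][:] = 3.0 * control["chr1"]
        peaks = [GenomicInterval("chr1", i * 100, i * 100 + 80) for i in range(100)]
        assert fit_genotype_scale(fused, control, peaks) == pytest.approx(3.0)
        noisy = CoverageTrack({"chr1": 10000})
        noisy.data["chr1"][:] = rng.poisson(2.5 * control["chr1"]).astype(float)
        m_prime = fit_genotype_scale(noisy, control, peaks)
        assert 2.3 <= m_prime <= 2.7


class TestFusion:
    def _tracks(self, a, b):
        t1 = CoverageTrack({"chr1": len(a)})
        t1.data["chr1"][:] = a
        t2 = CoverageTrack({"chr1": len(b)})
        t2.data["chr1"][:] = b
        return t1, t2

    def test_identity_when_equal_and_m_one(self):
        t1, t2 = self._tracks([3, 1, 4], [3, 1, 4])
        fused = fuse_replicates(t1, t2, m=1.0)
        np.testing.assert_allclose(fused["chr1"], [3, 1, 4])

    def test_reference_anchored_formula(self):
        t1, t2 = self._tracks([10.0], [20.0])
        assert fuse_replicates(t1, t2, m=2.0)["chr1"][0] == pytest.approx(10.0)

    def test_all_zero(self):
        t1, t2 = self._tracks([0, 0], [0, 0])
        assert fuse_replicates(t1, t2, 1.5)["chr1"].sum() == 0

    def test_namespace_mismatch_rejected(self):
        t1, _ = self._tracks([1], [1])
        t2 = CoverageTrack({"chr2": 1})
        with pytest.raises(ValueError):
            fuse_replicates(t1, t2, 1.0)

    def test_apply_genotype_scale(self):
        t1, _ = self._tracks([10.0, 4.0], [0.0, 0.0])
        out = apply_genotype_scale(t1, 2.0)
        np.testing.assert_allclose(out["chr1"], [5.0, 2.0])


class TestComputeCFR:
    def _tracks(self, ref_val, alt_val, n=100):
        ref = CoverageTrack({"chr1": n})
        ref.data["chr1"][:] = ref_val
        alt = CoverageTrack({"chr1": n})
        alt.data["chr1"][:] = alt_val
        return ref, alt

    def test_plain_ratio(self):
        ref, alt = self._tracks(5.0, 1.0)
        (rec,) = compute_cfr([GenomicInterval("chr1", 0, 10)], ref, alt,
                             min_alt_coverage=1.0)
        assert rec.cfr == pytest.approx(5.0) and not rec.capped

    def test_zero_alt_coverage_capped_at_300(self):
        ref, alt = self._tracks(5.0, 0.0)
        (rec,) = compute_cfr([GenomicInterval("chr1", 0, 50)], ref, alt)
        assert rec.cfr == 300.0 and rec.capped

    def test_equal_coverages_give_unity(self):
        ref, alt = self._tracks(7.0, 7.0)
        (rec,) = compute_cfr([GenomicInterval("chr1", 0, 60)], ref, alt,
                             min_alt_coverage=1.0)
        assert rec.cfr == pytest.approx(1.0)

    def test_invariant_to_joint_rescaling(self, rng):
        ref, alt = self._tracks(0.0, 0.0, n=500)
        ref.data["chr1"][:] = rng.uniform(5, 50, 500)
        alt.data["chr1"][:] = rng.uniform(5, 50, 500)
        regions = [GenomicInterval("chr1", i * 50, i * 50 + 40) for i in range(10)]
        base = compute_cfr(regions, ref, alt, min_alt_coverage=1.0)
        ref2, alt2 = self._tracks(0.0, 0.0, n=500)
        ref2.data["chr1"][:] = 7.3 * ref["chr1"]
        alt2.data["chr1"][:] = 7.3 * alt["chr1"]
        scaled = compute_cfr(regions, ref2, alt2, min_alt_coverage=7.3)
        for a, b in zip(base, scaled):
            assert a.cfr == pytest.approx(b.cfr)
            assert a.capped == b.capped


def test_self_normalization_is_identity():
    """A genotype normalized against itself must come out untouched:
    m = m' = 1 and CFR = 1 on every region (noise-free reading)."""
    import bindscape.simulate as sim
    from bindscape import SimConfig

    cfg = SimConfig(
        seed=3, genome_length=200_000, n_regions=25, n_background_peaks=12,
        noise=False, m_true=1.0, depth_ref=1.0, depth_alt=1.0, n_zero_alt=0,
    )
    fx = sim.build_fixture(cfg)
    tracks, regions = fx["tracks"], fx["regions"]
    bg_peaks = rudimentary_peak_find(tracks["control"], cutoff=20, min_gap=25)
    norm, sf = normalize_genotype(
        tracks["ref_rep1"], tracks["ref_rep1"], tracks["control"], regions, bg_peaks
    )
    assert sf.m == pytest.approx(1.0)
    norm2, sf2 = normalize_genotype(
        tracks["ref_rep1"], tracks["ref_rep1"], tracks["control"], regions, bg_peaks
    )
    records = compute_cfr(regions, norm, norm2, min_alt_coverage=1.0)
    for rec in records:
        assert rec.cfr == pytest.approx(1.0)
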