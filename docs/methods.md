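# Methods

`bindscape` quantifies how the loss of a transcription factor's
oligomerization capacity reshapes its genome-wide DNA binding. It was built
around the comparison of a wild-type factor with an oligomerization-dead
point mutant, both expressed constitutively in the same tissue and assayed by
ChIP-seq, with a non-transgenic control genotype providing background. The
package implements four linked analyses — occupancy normalization and the
coverage fold reduction (CFR), PWM-based binding-site landscape
characterization with a data-driven affinity threshold, site spacing, and
chromatin-accessibility stratification — together with a synthetic-data
generator that plants all of this structure with known ground truth.

## Coverage and the two-step normalization

Reads are reduced to their 5′ position and extended by a fixed fragment
length (default 130 bp) in read orientation; the per-base read count is the
number of extended reads covering each position, and the *coverage* of a
region is the area above that curve (the per-base sum). Tracks may equally be
supplied directly as bedGraph.

Comparing genotypes requires putting four libraries on one scale. This
proceeds in two regressions, both least squares through the origin — no
signal in one library should mean no signal in the other, so a free intercept
is physically unmotivated (it is available as an option):

1. **Intra-genotype** (replicates). Coverages of the bound regions in
   replicate 2 are regressed on replicate 1, giving `m = Σxy / Σx²`.
   Replicates are fused as `fused = (rep1 + rep2/m) / 2`, anchored on
   replicate 1. A symmetric variant that rescales both replicates to their
   geometric-mean depth is provided; both leave genotype-vs-itself
   normalization at the identity, which the tests pin down.
2. **Inter-genotype** (depth). The control genotype carries no
   transgene-driven signal, so intervals enriched in it are shared background.
   A rudimentary peak finder — maximal runs of signal at or above a cutoff
   (default 20), with sub-cutoff gaps shorter than `min_gap` (default 25 bp in
   the pipeline) merged — calls these background peaks on the control track.
   Regressing fused-genotype coverage on control coverage over them gives
   `m′`; dividing the fused track by `m′` puts both genotypes on the
   control's depth scale.

**CFR.** For each bound region, `CFR = cov_ref / cov_alt` on the normalized
tracks: how many-fold the mutant's occupancy is reduced. Regions with mutant
coverage below `min_alt_coverage` — by default the area one extended read
contributes, 130 — are assigned the cap value (default 300) and flagged;
ratios there are unstable or infinite. The cap is triggered by absolute
denominator coverage rather than by ratio magnitude so the rule is explicit
and testable; note this makes the cap (not the ratio) sensitive to joint
rescaling of both tracks, so `min_alt_coverage` must be expressed on the same
scale as the tracks.

## Binding-site landscape

Sites are scored by an L×4 position weight matrix in max-0 convention: each
position's best base scores 0, so the optimal L-mer scores 0 and every other
window is negative, down to `min_score` (sum of per-position minima). A
normalizer rescales arbitrary additive matrices into this convention by
subtracting per-position maxima. Scanning scores every offset on both strands
(reverse complement) and by default reports only the better strand per offset
(ties to +), avoiding double-counted palindromic hits.

**Affinity threshold.** Rather than an arbitrary cutoff, the threshold is
determined from the data. For each unit score window ([0;−1], [−1;−2], … down
to the matrix minimum), per-region site densities (sites/kb) in the bound
regions are compared with a *negative set* — for each bound region, a random
genomic interval of the same length, within `gc_tol` (default 0.05) of its GC
content, not overlapping any bound region; annotation category is recorded
but not constrained. Each window gets a one-sided Mann–Whitney test (bound >
negative); a window is significant when p < α (default 0.05, uncorrected per
window — a Benjamini–Hochberg option exists but is off by default) *and* the
bound-set median density exceeds the negative median. The threshold is the
deep edge of the maximal contiguous significant run starting at [0;−1]; if
the first window is not significant the result is "none". Contiguity from the
best window is assumed: a detached deep run would not describe an affinity
cutoff.

**Spacing.** The distance between two sites is the gap between their L-bp
footprints (`start_downstream − (start_upstream + L)`): 1 means one spacer
base, the configuration that most favours tetramer formation; 0 means
adjacency; negative gaps (overlapping footprints) are excluded from
histograms by default. Regions are ranked by CFR and split into ten
near-equal deciles (remainder to the lowest deciles; ties broken by region
rank then id for determinism); per decile, all pairwise gaps below 40 bp are
histogrammed, and the count of exactly-1-bp-gap pairs per region feeds the
pair-count analysis.

## Chromatin accessibility

A bound region is *open* when its centred half — the middle 50 %, computed
with floor division on both flanks — is entirely covered by the union of
DNase-hypersensitive intervals; a single uncovered base breaks openness
(strict reading of "entirely"). Quantitative DHS signal over a region is the
same area measure as ChIP coverage (a sum, not a mean, for consistency).
Outputs: closed fraction per CFR decile, Pearson correlation (with r², and
two-sided p from the t transform with n−2 df) between raw CFR and DHS signal
(a log10 option exists; raw is the default), and a Mann–Whitney contrast of
CFR between the lowest- and highest-DHS deciles (two-sided, as for all decile
contrasts; the threshold windows alone are one-sided by construction).

## Statistics

Mann–Whitney U uses mid-rank ties; the exact null distribution (full
enumeration) when both samples have n ≤ 8 without ties, and otherwise the
normal approximation with tie and continuity corrections (scipy's
implementation backs both paths; the exact path is verified against a full
combinatorial enumeration in the tests). Pearson p-values come from the
t transform. Decile machinery is shared across analyses.

## Synthetic data: what it emulates and what it does not

The generator emits every input the pipeline consumes — genome FASTA, PWM
TSV, regions BED, five bedGraph tracks, annotation BEDs, DHS BED + bedGraph,
and a ground-truth manifest — deterministically per seed.

Default study conditions: one 2-Mb chromosome at GC 0.36 (a gene-dense,
AT-rich plant genome); 300 bound regions of 500–900 bp; 100 control
background peaks; 200 expected extended reads per reference peak (triangular
peak kernel, width = region length); flat background of 0.05 expected
reads/bp; replicate distortion m = 1.5; genotype depths 1.2 (reference) and
0.8 (mutant) relative to the control; independent per-base Poisson noise on
expected counts (a read-level mode that emits actual reads exists for testing
the extension path); two regions with zero mutant occupancy to exercise the
CFR cap.

The planted fold reduction follows
`log f = log 2 + 1.2·(−best/15) + 1.25·pairs + 1.5·closed + ε`,
ε ~ N(0, 0.3), clipped to [1.3, 250]: weaker best sites, more 1-bp-spaced
pairs and closed chromatin all raise the fold reduction. Pair prevalence
(70/20/10 % for 0/1/2 pairs) and the ~3.5× per-pair effect were chosen so the
1-bp spacing enrichment concentrates three- to four-fold (or more) in the top
CFR decile — the qualitative structure the spacing analysis is meant to
detect. Closedness (35 % of regions) maps to DHS files directly: open
regions get an interval covering at least their centred half plus high
per-base signal; closed regions get nothing or a sub-centred-half fragment
plus low signal.

The generated PWM has one zero-weight consensus base per position (consensus
composition following the genome's, so GC-matched negatives exist at the
default tolerance) and mismatch penalties uniform in 1.5–5.5 score units.
That range is deliberate: random genomic background stays sparse above −21
(< 1 site/kb) so planted structure dominates, while single substitutions as
small as ~1.5 keep every unit score window constructible for the site
planter. The planter descends from the consensus by greedy single *and
paired* base substitutions until the window's score is within tolerance of
the target; achieved (not target) scores are recorded in the manifest and
re-verified by re-scoring in the tests.

Two site-planting modes serve two different recovery questions. The default
*landscape* mode varies best-score targets (uniform on [−15, 0]), extra
weaker sites and 1-bp-gap pairs across regions — the substrate for the decile
analyses. The *window_uniform* mode instead plants, per region and per unit
score window above a configurable floor, one site with probability 0.7 — the
substrate for threshold recovery, whose per-window median-density rule needs
a majority of regions to carry a site in every enriched window. One fixture
cannot provide both the per-window occupancy the median rule needs and the
across-region best-score variation the decile analyses need, so each analysis
is exercised on the fixture built for it.

Densely planted regions carry an artifact: windows overlapping planted
footprints score in the just-sub-floor band about twice as often as raw
genome, which would smear the planted floor. In window_uniform mode the
generator therefore edits chance hits in the band [floor−6, floor) out of
bound regions, touching only positions not covered by any supra-floor window
on either strand — so the shared background above the floor is provably
unchanged, and the per-window site content around the floor is exactly the
planted truth. Null fixtures (`site_mode="none"`) are left untouched, keeping
bound regions statistically exchangeable with the negative set.

What the generator does *not* emulate: fragment-length variation, GC bias,
mappability, duplicated reads, peak-shape diversity, correlated noise between
replicates, or motif clustering beyond what is planted. Passing recovery
tests therefore demonstrates that the estimators are correct and well
calibrated under the stated noise model, not that real libraries meet that
model.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; touching intervals do not
  overlap. bedGraph records may not overlap (the pipeline's own outputs never
  do); parse errors name the offending line.
- Score-window binning: window k holds scores in (−(k+1), −k]; score 0 falls
  in the best window.
- Strand ties in scanning go to + with a 1e-9 tolerance absorbing
  summation-order noise on palindromes.
- Regressions refuse all-zero predictors; correlation refuses zero variance;
  decile machinery refuses fewer than 10 records; N-containing windows score
  −∞ and are skipped, and all-N sequences have no GC content.
- Windows where both density sets are identically constant short-circuit to
  p = 1 (no evidence) rather than calling a degenerate rank test.
- The pipeline falls back to a configurable scan threshold (default −20) when
  threshold determination returns "none", logging the fallback.

## Problem sizes

Default analyses (2 Mb, 300 regions) complete in seconds on one CPU; the
full test suite, including end-to-end recovery and 20-repeat null studies,
runs in about a minute, and `scripts/acceptance.py` in well under a minute.
These sizes were chosen so every decile holds ~30 regions — enough for the
rank tests to resolve the planted effects — while keeping iteration fast.

## Known limitations

- The exact replicate-fusion convention is reference-anchored by design
  choice; the symmetric alternative is exposed but untested against any
  external implementation.
- The cap rule keys on absolute mutant coverage, so cap decisions change
  under joint rescaling unless `min_alt_coverage` is rescaled too.
- The negative-set sampler can fail (with a clear error) on genomes whose
  composition cannot GC-match unusually extreme bound regions at the chosen
  tolerance.
- Threshold determination assumes a contiguous significant run; biological
  situations with genuinely bimodal affinity enrichment would be truncated at
  the first gap.
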