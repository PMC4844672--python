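# bindscape

Differential ChIP-seq occupancy and binding-site landscape analysis for
transcription-factor oligomerization studies.

Some transcription factors bind DNA not as isolated dimers but as
higher-order assemblies. When the oligomerization surface is broken by point
mutation, genome-wide binding collapses unevenly: some regions lose the
factor almost entirely, others barely notice. `bindscape` quantifies that
unevenness and asks what distinguishes the regions that depend on
oligomerization — weak binding sites, clustered sites with a particular
spacing, or closed chromatin.

The package is organised as an analysis project: the library under
`src/bindscape/` holds every computation, the numbered scripts under
`analysis/` drive the study end-to-end on synthetic data with known ground
truth, and `tests/` verifies each step against independent oracles and
planted-truth recovery.

## The statistics at the core

**Coverage fold reduction (CFR).** For genotypes *ref* (wild-type factor)
and *alt* (oligomerization-dead mutant), each assayed in duplicate next to an
untransformed control, coverage of a bound region is the area above the
extended-read count curve. After two-step normalization — replicate fusion via
a through-origin regression slope *m* (`fused = (rep1 + rep2/m)/2`), then
depth correction via the slope *m′* of fused vs control coverage over
control-called background peaks —

&nbsp;&nbsp;&nbsp;&nbsp;CFR = cov_ref / cov_alt,

with regions whose mutant coverage falls below one extended-read equivalent
capped at 300. High CFR = binding that needs oligomerization.

**Affinity threshold.** Binding sites are 19-bp windows scored by a PWM in
max-0 convention (optimal site 0, worst about −60). Instead of an arbitrary
cutoff, per-region site densities in unit score windows ([0;−1] … down the
scale) are compared between bound regions and GC- and length-matched random
regions by one-sided Mann–Whitney tests; the threshold is the deep edge of
the contiguous significant run starting at the best window.

**Landscape and chromatin.** Regions are stratified into CFR deciles and
related to best site score, site density, 1-bp-spaced site pairs (the
tetramer-friendly configuration; distances are inter-footprint gaps), the
fraction of regions whose centred half is not entirely DNase-accessible, and
the Pearson correlation between CFR and quantitative DHS signal.

## Worked example

```sh
python analysis/01_simulate_study.py
python analysis/02_normalize_and_cfr.py
python analysis/03_motif_landscape.py
python analysis/04_chromatin_state.py
```

The first script plants a 2-Mb study (300 bound regions, two genotypes × two
replicates + control, Poisson noise, known per-region fold reductions). The
second recovers the normalization and CFR:

```
normalization coefficients (planted -> recovered):
  m       1.5 -> ref 1.4994, alt 1.4967
  m'      ref 1.2 -> 1.1994; alt 0.8 -> 0.8007
median CFR relative error: 1.24% over 298 regions
capped regions (CFR set to 300): 2 (planted zero-occupancy: 2)
```

i.e. the replicate and depth distortions are recovered to a fraction of a
percent and the per-region fold reductions to ~1% median error, with exactly
the two planted zero-occupancy regions capped. The third script recovers the
planted affinity floors and shows the spacing structure:

```
1-bp spacing counts per decile [0, 0, 0, 1, 6, 7, 16, 14, 33, 49]; top decile is
7.5x the per-decile median (three- to fourfold structure planted)
planted score floor -20 -> recovered threshold -20
planted score floor -25 -> recovered threshold -25
unplanted null fixtures: threshold 'none' in 10/10 repeats
```

and the fourth ties fold reduction to chromatin state:

```
closed fraction per CFR decile (low -> high): ['0%', '0%', '0%', '0%', '43%',
'70%', '57%', '70%', '63%', '87%']
CFR vs DHS signal: r = -0.357 (r^2 = 12.7%, p = 1.9e-10)
```

Regions that lose binding most when oligomerization is broken are exactly
those with weak or clustered sites in closed chromatin. Tables land under
`results/`; the bulky generated inputs under `scratch/`.

A thin CLI wraps the same library: `bindscape simulate --seed 42 --outdir
fixture/` and `bindscape run --config run.cfg --outdir out/` (flat
`key = value` config; see `bindscape run --help`).

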