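# Methods

This note documents the models and procedures implemented in `sccnv`, the
parameters that matter, the design choices made where several readings were
defensible, and what the synthetic benchmarks do and do not demonstrate.

## Read-count simulator

A genome is reduced to chromosome lengths and a GC fraction per fixed 10-kb
window, generated as a bounded AR(1) walk (lag-1 autocorrelation 0.9 by
default, values clipped to [0.30, 0.70]). Two stock genomes are provided:
hg19-proportional autosomes at 1/20 scale (~150 Mb; the default, so that
5000-bin analyses and Mb-scale CNVs stay meaningful at desk scale) and at
full scale (~2.9 Gb; used by the size-sweep benchmark, whose 20 spiked CNVs
of up to 15 Mb cannot fit on the scaled genome — placement is restricted to
less than half the genome).

A cell is simulated window by window. The expected read mass of window *w*
is proportional to `cn_w * gc_weight(gc_w)` where `cn_w` is the clone's
(length-weighted) copy number over the window and
`gc_weight(gc) = max(1 - strength*(gc-0.5)^2, 0.05)` is a unimodal GC
preference curve (default strength 2.0, a mild mid-GC preference). Counts
are negative-binomial with `var = mu + dispersion*mu^2` (Poisson at
dispersion 0); read starts are uniform within a window, except that windows
straddling a copy-number boundary place reads according to the bp-level
copy number, so a CN=0 stretch emits exactly zero reads. Finally a
`dup_rate` fraction of the raw reads are appended as exact-position copies
of existing reads, mirroring removal by position-based deduplication
(single-end data); `n_reads` is therefore the expected number of template
reads, and raw output is `~ n_reads/(1-dup_rate)`.

**Noise calibration.** The defaults (`gc_bias_strength=2.0`,
`dispersion=0.22`, `dup_rate=0.10`) are anchored to one quantity: a diploid
cell sequenced to 400,000 raw reads and profiled in 5000 bins on the default
genome should have MAPD ≈ 0.26, the noise level of a good-quality
tagmentation-based single-cell library. The dispersion was found once by
bisection against that anchor and frozen. Because dispersion acts at the
10-kb window level, wider bins average it down; noise at other genome
scales or bin counts follows from the model rather than being fit.

**What the simulator does not model.** Base-level sequence, alignment,
mappability artifacts, chimeric reads, and locus-specific (reproducible)
amplification bias. Real single-cell libraries show spatially correlated
bias that survives GC correction; synthetic benchmark results are therefore
an upper bound on real-data accuracy at the same depth and noise level.

## Three-clone preset

The preset emulates a paired primary/relapse tumor. All tumor cells share
arm-level gains (chromosomes 5, 6p, 7, 8q, 15q) and losses (6q, 8p). Minor
clones B and C additionally carry a 1q gain, a 10q loss and a terminal 14q
loss; C — the relapse-dominating state — carries the 1q gain at a higher
level (CN 4 vs 3) and an extended 10q loss, making B a transitional state
of C and keeping the two separable in the clustering feature space.
Region coordinates are fractions of chromosome length, so the preset maps
onto any genome with ≥ 15 chromosomes. Default mixtures: primary = 87 A +
11 B + 5 C + 3 normal (106 cells; minor clones are 16/103 = 15.5% of tumor
cells), relapse = 12 B + 102 C + 4 normal (118 cells).

## Binning and GC normalization

Bin count follows the coverage rule `n = round(UMDR/target)` with target
30–180 reads per bin (default 60), clamped to [100, 50000]. Bins are
equal-width within chromosomes (allocated across chromosomes by length,
largest-remainder); an optional per-window weight track instead equalizes
cumulative expected read mass per bin, emulating variable-width binning
against a read-depth reference. All coordinates are 0-based, half-open; a
read belongs to the bin containing its start; duplicates are keyed on
(chrom, start) per cell.

GC normalization fits count against bin GC with lowess (span 0.3, 3
robustifying iterations — chosen as a common robust default, since bins
inside CNVs act as outliers to the fit), divides by the fit (floored at
`1e-6 x mean count`) and rescales to mean 1. CNV-aware masking before the
fit is deliberately not done; when more than 30% of bins deviate over
two-fold from the median, a note is logged because the diploid assumption
of the plain fit is then strained.

## Segmentation and integer copy number

CBS operates on untransformed ratios (deep deletions drive ratios toward 0,
where logs degenerate). Per chromosome the arc `[i, j)` maximizing the
two-sample pooled-variance t statistic (variance floored at 1e-8; ties
broken toward smallest `i`, then `j`; arc and complement each at least
`min_width = 2` bins) is tested by permutation: the chromosome's bins are
fully shuffled `nperm = 1000` times and the max-arc statistic recomputed;
the split is accepted at p < alpha = 0.01. Permutations stop early once the
exceedance count reaches `ceil(alpha*nperm)` (the split can no longer be
significant) and accept early when no exceedance occurs in the first 300
shuffles (p < 1/300); both rules are deterministic given the seed. After
recursion, adjacent segments whose means differ by less than
`undo_sd x MAD(bin-to-bin differences)` (undo_sd = 1.0) are merged,
smallest difference first.

Integer calls scale segment means by the length-weighted median segment
ratio and round: `cn = round(2*mean/baseline)`, clipped to [0, 12]. The
assumed ploidy is fixed at 2; cells with less than 30% of the genome at
baseline are flagged as possibly mis-scaled rather than re-fit, since the
workflow treats CNV-free cells as diploid normals and performs no ploidy
search.

## QC metrics

MAPD is computed on linear ratios (the alternative log2 reading is
available by flag); consecutive pairs never straddle chromosomes. Filter
thresholds `UMDR >= 300,000` and `MAPD <= 0.45` are inclusive at the
boundary. The Lorenz curve uses deduplicated reads down-sampled without
replacement to 100,000, counted in fixed 60-kb bins over the whole genome
(zero-count bins included), sorted ascending; Gini = 1 - 2 x trapezoidal
area under the curve.

## Benchmarks

**Size sweep.** For each size in {1, 2, 3, 5, 10, 15} Mb: 20 non-overlapping
CNVs (CN 1 or 3, uniform placement) are spiked into full-scale autosomes,
one cell is simulated at 300,000 expected unique reads under default noise,
and calling runs at 5000, 10,000 and 20,000 bins; 5 replicates. Matching
requires the same direction (gain to gain, loss to loss) and overlap of at
least 50% of the truth segment's length; reciprocal and detected-based
readings are available as options. Greedy matching by descending overlap;
each truth segment validates at most one call. Sensitivity rises steeply
between 1 and 2 Mb (a 1-Mb CNV spans < 2 bins at 5000 bins and is usually
merged away or missed), reproducing the regime where roughly 80% or more of
CNVs of at least 2 Mb are recovered while FDR stays low.

**Saturation.** A major-clone (aneuploid) cell is simulated with ~2.3 M
unique reads, down-sampled without replacement to the fixed schedule 3e4 …
2e6, and copy number is called at each depth with the same 5000-bin scheme.
The abnormal-bin set at the deepest scheduled depth is the reference; the
recovered fraction per depth is smoothed by lowess over log-depth (span
0.4), made monotone by a running maximum, and the saturation point is the
smallest scheduled depth reaching 99% of the full-depth value — a concrete
operationalization of the "inflection point" of a monotone curve. With
arm-scale events the curve is flat at 1.0 from the lowest depths: a handful
of reads per bin already places the large segments correctly, so the
saturation point lands at or near the bottom of the schedule, comfortably
below 300,000 reads.

**Clonal recovery.** The full preset population (106 + 118 cells at 300,000
unique reads) is called at 5000 bins; normal cells (no call >= 3 Mb and
<= 2% abnormal bins) are set aside; tumor cells are clustered with Ward
linkage (scipy, `ward` on Euclidean distances = hclust/ward.D2) at k = 3 on
segment ratios restricted to the chr1/10/14 analogues. k is user-supplied
(default 3; a silhouette-based suggestion exists but is never applied
silently). Under default conditions the clustering matches the generating
clones (ARI 1.0 in the configurations exercised by the tests), the minor
clones comprise ~15.5% of primary tumor cells, and the C-dominated cluster
grows from ~5% of primary to ~90% of relapse tumor cells.

## Problem sizes and determinism

Default analyses use 5000 bins; the acceptance script's sweep covers 90
cell-analyses, and the clonal scenario 224 cells, sized to run in minutes
on one CPU. Every stochastic step (genome, spikes, cells, CBS permutations,
down-sampling, sub-seeds per cell) derives from a single master seed via
`numpy.random.SeedSequence`; reruns with the same configuration produce
byte-identical outputs, which the pipeline verifies by recording SHA-256
checksums in its manifest.

## Known limitations

- Count-level simulation cannot expose alignment- or mappability-driven
  false calls; real-data FDR is expected to exceed the synthetic estimate.
- The integer-CN baseline assumes the dominant state is diploid; genomes
  with whole-genome duplication would be systematically mis-scaled.
- MAPD's exact published formula varies between platforms (linear vs log2);
  both are implemented, linear being the default used by the filter
  threshold 0.45.
- Consensus-based ancestry hints use a superset rule on abnormal-bin sets;
  they suggest, but cannot establish, clonal phylogeny.
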