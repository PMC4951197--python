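# Methods

This note documents the models and procedures implemented in `grosv`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); all region
output is BED-like TSV. Chromosome-level containers are pandas DataFrames
with `chrom`/`start`/`end` columns. bedGraph signal is distributed to
fixed-width bins mass-conservingly by base-pair overlap (a record spanning
two bins contributes proportionally to each); minus-strand files that
encode signal as negative values, as genome browsers display them, are
rectified on read. Records on chromosomes absent from the active
chromosome-sizes table are skipped with a warning count rather than
failing, because annotation sources routinely mix contig sets; a record
extending past its chromosome end is an error, because it indicates the
wrong genome build.

Proximity queries (`windowed_overlap`) flag a region when its distance to a
feature is at most the window, with touching intervals at distance 0 — so a
1-kb window captures everything up to and including 1 kb away. Background
windows for the binomial test instead require at least 1 bp of true
overlap, since a tile that merely abuts a feature contains none of it.

## Convergent transcription (convT)

A convT region is a maximal run of base pairs covered by both a plus- and a
minus-strand transcript, kept when at least 100 bp long (`convt_min_overlap`).
Operationally this is the intersection of the two strands' transcript-footprint
unions; overlapping emissions from multiple samples are combined by union at
gap 0. Working on strand unions rather than transcript pairs means that two
short antisense transcripts jointly covering a 100-bp run of a gene count as
convT even if neither alone overlaps by 100 bp; this matches the per-bp
"both strands transcribed" reading and is what the bitmap oracle in the
test-suite checks.

The convT *level* is `min(signal⁺, signal⁻) / length` in reads per bp —
the weaker (usually antisense) strand limits how much truly convergent
transcription a region sustains. Regions are ranked into quartiles of this
level by rank, ties broken by genomic order, so that degenerate inputs
(all levels equal) still yield four usable groups.

Enhancer-RNA candidates are transcripts shorter than 15 kb that either have
a divergent partner (an opposite-strand transcript whose start lies within
1 kb of theirs — "bidirectionality" is not defined numerically anywhere
authoritative, so the 1-kb divergent-start window is this package's
operationalization, exposed as a parameter) or overlap a supplied
enhancer-mark region set.

## Pol2 stalling

Per gene, the 50-bp-binned sense-strand signal is z-scored (zero mean, unit
variance; a zero-variance gene short-circuits to "no stalls") and segmented
with PELT. The cost of a segment is its sum of squared deviations from the
segment mean — the Gaussian mean-change cost with variance fixed at 1,
which the z-scoring justifies — and each changepoint costs β = 2·ln n:
BIC counting both the new segment mean and the changepoint location as
parameters. PELT's pruning is exactness-preserving for this cost, and the
test-suite verifies the pruned solver against an unpruned O(n²) dynamic
program on random series, comparing both the breakpoints and the optimal
cost. Ties in the optimum are broken toward the earlier candidate, i.e.
fewer/earlier changepoints.

A segment is reported as stalled when its **raw** (pre-scaling) mean
exceeds both the gene's median raw bin value and the gene's empirical
`quantile` of raw bin values — 0.90 for nascent-transcription signal, 0.80
for ChIP input, which has a higher background. The quantile is taken over
the gene's bin values (not over segment means or over genes); this reading
is a deliberate choice among plausible alternatives and is exposed as the
`quantile` argument. Unstranded (ChIP) input is handled by scanning every
gene on the single supplied track. Genes shorter than 4 bins are skipped
with a logged count; segment coordinates are clipped to the gene. Calls
from multiple samples are merged at a 100-bp gap.

Detected transcripts can be filtered by annotation match before stalling
analysis: a detected transcript is kept when some same-strand annotation
(a) covers at least 5% of the detected length, (b) lies at least 50% inside
the detected transcript, and (c) starts (strand-aware TSS) within 10 kb of
it. The 50% clause is read as a containment requirement on the annotation,
not a second threshold on the detected transcript — otherwise it would
subsume clause (a) and make the 5% threshold vacuous.

## Breakpoints and RSS motifs

Breakpoints are single coordinates (SV ends). Motif classification extends
each by 10 bp to a 21-bp window and scans both strands with a PWM at every
offset. Log-odds scores use a small background-weighted pseudocount
(10⁻³) so consensus-style matrices with zero cells stay finite, and are
scaled to integers (×1000) so that the scanned score and the null
distribution live on the same grid; the null distribution of the window
score under the 0-order background is then computed exactly by dynamic
programming (position-wise convolution), as FIMO does. The window p-value
is the minimum per-position match p over both strands, compared to the
0.003 cutoff without multiple-position correction — per-match semantics.
The per-window false-positive rate is therefore bounded by roughly
0.003 × 2 × (21 − w + 1), which the test-suite checks empirically on
background sequences. Windows containing non-ACGT characters, or
breakpoints on chromosomes missing from the genome, are NA and excluded
from R/NR analyses.

Stitching chains successive breakpoints on a chromosome whenever their
positions differ by at most 1 kb (single linkage), so the breakpoint count
is conserved exactly and increasing the distance can only coarsen the
regions. A stitched region's RSS class prioritizes R over NR over NA,
because regions — not individual ends — carry the classification.
Recurrence bins label a region by the highest cutoff its member count
exceeds (default cutoffs 1, 2, 4 giving classes "1", ">1", ">2", ">4").

Feature-overlap fractions use a 1-kb window by default. Intragenic analyses
(stalling is only defined inside gene bodies) first restrict the regions to
those overlapping a gene. Expression stratification splits host genes into
rank quartiles of maximum RPKM across samples and reports the overlap
fraction per quartile.

## TADs

The directionality index is computed per bin of a symmetric, binned (50-kb)
contact matrix over a configurable window (default 40 bins = 2 Mb):
A and B are the contact sums to the window upstream and downstream
respectively, E = (A+B)/2, and DI = sign(B−A)·((A−E)²/E + (B−E)²/E), zero
when A+B = 0; edge bins use truncated windows. Boundary calling is
deliberately simple and deterministic rather than an HMM: bins are labelled
+/−/neutral against a threshold at the profile's median |DI|, same-sign
labelled bins group into runs (neutral bins do not break a run), and a
boundary is placed at the first bin of a sustained-positive run that
follows a sustained-negative run (both ≥ `min_size_bins`, default 3).
A flat matrix yields a single whole-chromosome domain. This is a
simplification adequate for the quartile analyses the domains feed; it is
not a general-purpose TAD caller.

TADs containing at least one breakpoint are quartiled by breakpoints per
bp with exclusive-lower/inclusive-upper ranges at the 25/50/75 empirical
percentiles. Feature span per TAD is either the plain covered fraction or,
in normalized mode, feature bp divided by transcribed bp within the TAD
(union of transcripts); a TAD with no transcription has no normalized span
and is reported missing. Quartile enrichment flags TADs with span above the
all-TAD median as "high" and applies the upper-tail hypergeometric test per
quartile against the whole population.

## Statistics

- **Binomial enrichment**: the universe is tiled into non-overlapping 1-kb
  windows, clipped at universe-piece ends, with clipped windows shorter
  than 500 bp dropped; p0 is the fraction of tiles sharing ≥ 1 bp with the
  feature, and the p-value is the exact upper binomial tail. p0 = 0 with
  observed successes yields a degenerate near-zero p with a warning.
- **Hypergeometric / Fisher**: exact tails via scipy; the Fisher odds ratio
  is the sample ad/bc with a normal-approximation CI on the log scale using
  Haldane's 0.5 correction when any cell is zero; a fully zero margin makes
  the OR undefined (NaN).
- **Wilcoxon rank-sum with shift**: exact p when n+m ≤ 20 (falling back to
  the normal approximation with continuity correction when ties preclude
  the exact path, and always above that size); the location estimate is the
  Hodges–Lehmann median of pairwise differences with a CI from the ordered
  pairwise differences at the normal-approximation ranks, as R's
  `wilcox.test(conf.int=TRUE)` computes it; the fold change of medians is
  reported on the linear scale and is missing when the denominator median
  is 0.
- **Resampling null**: each of 1000 resamples re-places every query region
  uniformly within a universe piece large enough to host it — sizes
  preserved, mutual overlap permitted (the observed statistic is a
  fraction, insensitive to rare self-overlap at genome scale) — and the
  empirical p uses the +1 (Davison–Hinkley) estimator so p ≥ 1/(B+1) > 0
  always. The z-score standardizes the observed fraction against the null
  mean and SD; because the z-test presumes an approximately normal null,
  the null's skewness is reported alongside as a diagnostic rather than
  silently trusted.

## Width analyses and metaprofiles

Peak filters use strict inequality ("score above 15" excludes 15 exactly).
Top-5%-widest sets take ⌈0.05·n⌉ regions by width with ties at the cut
resolved by genomic order; their co-occurrence is a 2×2 Fisher table over
base pairs within the union of all candidate regions (wide-stall ×
wide-peak coverage), a construction documented here precisely because the
analogous external tools leave it implicit. A stall or peak overlapping
TSS of both comparison classes contributes to both samples. TSS signal is
log2(1 + mean bin value) over ±1-kb windows — the +1 pseudo-count keeps
all-zero tracks at 0. Metaprofiles re-bin each active gene (RPKM > 0.5,
length ≥ 100 bp) to 100 equal-length bins on an integer grid that
partitions the gene's signal mass exactly, take per-bin densities, reverse
minus-strand genes so bin 0 is the TSS, average over genes and normalize
the profile to sum to 1.

## Synthetic data

The generator emulates, at desk scale, the statistical structure the
analyses assume. Defaults: 2 chromosomes × 1 Mb, 60 genes of 5–30 kb placed
without overlap on a 50-bp grid (grid alignment keeps planted structure
commensurate with signal bins), per-gene expression lognormal around
RPKM 5, bin counts negative-binomial with dispersion 10 — GRO-seq bin
counts are overdispersed, so Poisson noise would be too easy — with mean
`baseline_mu·rpkm/5` inside genes (default baseline 10) and `baseline_mu/20`
elsewhere. 30% of genes receive an antisense partner fully inside the gene
(every convT region therefore traces to a known partner, and the truth
table is exact geometry); 30% receive a stall segment of 500–2000 bp
(10–40 bins) whose mean is multiplied by `stall_shift` (default 10).
Breakpoints are point coordinates drawn with odds `feature_odds`
(default 3) of landing inside a designated feature union — giving the
closed-form inside probability wf/(wf+1−f) — and a subset carries the
planted RSS heptamer consensus (CACAGTG) in a uniform-random synthetic
genome sequence generated at run time. Contact matrices use a separate
10-Mb axis (real TADs are ~1–2 Mb, far larger than the signal-genome
chromosomes) with `n_tads` equal blocks, Poisson counts around
`hic_mu/(1+d)` within blocks and 1/enrichment of that between blocks; the
1/(1+d) distance decay is minimal realism so the directionality index is
exercised — its exact form is immaterial to the analyses.

All streams are integer-seeded per component, so outputs are byte-identical
across runs and platforms.

What the generator does **not** emulate: mappability and GC structure,
transcript isoform complexity, signal autocorrelation beyond segment means,
realistic SV subtype composition, Hi-C matrix normalization artifacts, and
sequence realism beyond the planted motif. Passing recovery tests on this
generator therefore demonstrates correctness of the algorithms under their
stated model, not performance on real sequencing data.

## Benchmark problem sizes

The acceptance script runs: 50 random series (n ≤ 200) for the PELT/DP
equivalence; 100 genes at shift 10 for stall recovery (mean Jaccard
reported); 200 random transcripts for the convT bitmap equivalence; 300
breakpoints for stitching invariants and for the odds-3 enrichment
recovery (with a 1000-resample null); 1000 null simulations of 200
breakpoints over a 15% feature set for type-I calibration — at that grid
the exact test's attained size is 0.0498, so the discreteness of the
binomial does not confound the calibration estimate; and two- and
five-block contact matrices at enrichment 3 for boundary recall. These
sizes give stable estimates in well under a minute.

## Known limitations

- The TAD caller's sign-run segmentation has no notion of nested domains
  and depends on the median-|DI| threshold; real contact maps may need an
  HMM-based caller.
- The exact motif p-value DP assumes a 0-order background and independent
  positions.
- `annotation_match_filter` and the eRNA bidirectionality window encode
  specific readings of loosely specified criteria (documented above); both
  are parameterized.
- The resampling null preserves region sizes but not chromatin context
  beyond the supplied universe; choosing the universe (whole genome vs
  gene space) is the analyst's modelling decision and changes p0
  materially.
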