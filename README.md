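# grosv

Transcription-feature analysis of structural-variant (SV) hotspots from
stranded nascent-transcription signal.

In precursor B-cell acute lymphoblastic leukemia, SV breakpoints cluster in
genomic regions with distinctive transcriptional features: **convergent
transcription** (convT — the same locus transcribed on both strands) and
**RNA polymerase II stalling** (a locally elevated signal segment inside a
gene body). Some breakpoints additionally carry a **recombination signal
sequence (RSS)**-like heptamer motif, the recognition site of the RAG
recombinase. `grosv` implements the full computational pipeline that turns
stranded GRO-seq-style signal tracks, transcript annotations, breakpoint
coordinates and a Hi-C contact matrix into these feature calls and into
quantified, significance-tested enrichment statements — together with a
synthetic-data generator so that every stage is testable without any
external download.

## What it computes

- **convT regions** — maximal runs of opposite-strand transcript overlap
  ≥ 100 bp; the convT *level* of a region is
  `min(signal⁺, signal⁻) / length` (the weaker strand's size-normalized
  signal).
- **Pol2 stalling segments** — per gene, the 50-bp-binned sense-strand
  signal is z-scored and segmented with **PELT**, the exact pruned dynamic
  program minimizing

  `Σ_segments Σ_i (x_i − x̄_seg)² + β·(number of changepoints)`,  β = 2·ln n

  (BIC with the changepoint counted as a parameter). A segment is *stalled*
  when its raw mean exceeds both the gene median and the gene's 90%
  (nascent signal) or 80% (ChIP) raw-bin quantile; calls are merged at a
  100-bp gap.
- **Breakpoint classification and stitching** — each breakpoint's 21-bp
  window (±10 bp) is scanned on both strands with a PWM; the match p-value
  is exact (dynamic programming over the integer-scaled log-odds score
  distribution under the background), and status is R iff p ≤ 0.003.
  Breakpoint ends within 1 kb chain into stitched regions whose member
  count defines recurrence (1, >1, >2, >4).
- **TADs** — the directionality index
  `DI_i = sign(B−A)·((A−E)²/E + (B−E)²/E)`, with A/B the upstream/downstream
  contact sums in a window and E = (A+B)/2, segments a 50-kb contact matrix
  at sustained negative→positive sign transitions; TADs with breakpoints are
  quartiled by breakpoints/bp and their feature span quantified.
- **Statistics** — exact binomial enrichment against a 1-kb-window
  background, hypergeometric and Fisher tests, Wilcoxon rank-sum with
  Hodges–Lehmann shift and CI, and a 1000-fold resampling null with
  empirical p and z-score.
- **Width analyses** — peak-width comparisons at stall sites (score > 15
  filter), top-5%-widest co-occurrence, TSS signal stratification, and
  length-normalized 100-bin gene metaprofiles.

## Worked example

```python
from grosv.simulate import (SimulationSpec, simulate_genome, simulate_tracks,
                            simulate_breakpoints)
from grosv.convt import detect_convt, quantify_convt_regions
from grosv.stalling import call_stalls, merge_stalls
from grosv.breakpoints import stitch, breakpoint_feature_overlap
from grosv.stats import binomial_enrichment, sampling_null
from grosv.intervals import as_regions

spec = SimulationSpec(seed=1)                      # 2 Mb genome, 60 genes
chrom_sizes, transcripts = simulate_genome(spec)
plus, minus, truth_stalls, truth_convt = simulate_tracks(spec, chrom_sizes, transcripts)

convt = quantify_convt_regions(detect_convt(transcripts, 100), plus, minus)
stalls = merge_stalls(call_stalls(transcripts[transcripts["kind"] == "gene"], plus, minus))
print(f"convT regions: {len(convt)} (median level {convt['level'].median():.3f} reads/bp)")
print(f"stall regions: {len(stalls)}")

bps = simulate_breakpoints(spec, chrom_sizes, convt)   # odds 3 of landing in convT
regions = stitch(bps, distance=1000)
frac, flags = breakpoint_feature_overlap(regions, convt, window=1000)
universe = as_regions([(c, 0, L) for c, L in chrom_sizes.items()])
res = binomial_enrichment(int(flags.sum()), len(flags), convt, universe)
emp = sampling_null(regions, universe, convt, n_resamples=1000, seed=1, window=1000)
print(f"stitched regions: {len(regions)}; fraction near convT: {frac:.3f}")
print(f"background p0={res.p0:.3f}, binomial p={res.p_binomial:.2e}, "
      f"empirical p={emp.p_empirical:.4f}, z={emp.z:.1f}")
```

Output:

```
convT regions: 18 (median level 0.075 reads/bp)
stall regions: 22
stitched regions: 251; fraction near convT: 0.080
background p0=0.037, binomial p=1.20e-03, empirical p=0.0130, z=2.6
```

The generator placed breakpoints with 3:1 odds of falling inside convT
regions covering ~2.7% of the genome, so ~8% of stitched regions sit within
1 kb of convT against a 3.7% background — an enrichment both the exact
binomial test and the 1000-fold resampling null flag as significant, and
with concordant p-values.

The same pipeline is scriptable from the shell (`grosv simulate`,
`grosv convt`, `grosv stall`, `grosv classify-rss`, `grosv stitch`,
`grosv overlap`, `grosv enrich`, `grosv tads`, `grosv metaprofile`);
see `grosv --help`.

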