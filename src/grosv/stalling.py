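"""RNA-polymerase-II stalling detection by change-point analysis.

A gene's binned sense-strand signal (50-bp bins) is z-scored and segmented
with PELT, an exact pruned dynamic program minimizing within-segment sum of
squared deviations plus a per-changepoint BIC penalty (``2·ln n``, the
changepoint counted as a parameter alongside the segment mean).  Segments
whose raw-signal mean exceeds both the gene median and a per-gene raw-bin
quantile (90% for nascent-transcription signal, 80% for noisier ChIP input)
are reported as stalled; calls from multiple samples are merged at a 100-bp
gap.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .intervals import merge_intervals
from .track import StrandedBinnedTrack

logger = logging.getLogger(__name__)

STALL_COLS = ["chrom", "start", "end", "gene_id", "segment_mean", "source"]


def pelt_mean(series, penalty: float) -> list[int]:
    """Exact changepoints in the mean of ``series`` under an SSE cost.

    Minimizes ``sum_segments SSE(segment) + penalty * n_changepoints`` with
    PELT pruning (the SSE cost is superadditive, so pruning keeps exactness).
    Returns the sorted segment boundaries ``t`` (each segment is
    ``[t_prev, t)``), excluding the trailing boundary ``n``.  A constant
    series yields no changepoints.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have length >= 2")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    if np.ptp(x) == 0 or not np.isfinite(penalty):
        return []
    cum = np.concatenate(([0.0], np.cumsum(x)))
    cum2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(s: np.ndarray, t: int) -> np.ndarray:
        length = t - s
        return (cum2[t] - cum2[s]) - (cum[t] - cum[s]) ** 2 / length

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cand = np.array([0], dtype=int)
    for t in range(1, n + 1):
        costs = f[cand] + seg_cost(cand, t) + penalty
        best = int(np.argmin(costs))
        f[t] = costs[best]
        prev[t] = cand[best]
        keep = f[cand] + seg_cost(cand, t) <= f[t]
        cand = np.append(cand[keep], t)
    cps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def scale_gene_signal(raw: np.ndarray) -> np.ndarray:
    """Z-score a gene's raw bin values (zero mean, unit variance).

    A zero-variance gene maps to all zeros, which short-circuits to "no
    changepoints" downstream.
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def call_stall_segments(
    gene,
    track: StrandedBinnedTrack,
    quantile: float = 0.90,
    source: str = "groseq",
    min_bins: int = 4,
) -> pd.DataFrame:
    """Stalled segments of one gene from one signal track.

    ``gene`` is any object with ``chrom``, ``start``, ``end``, ``name``
    attributes (a transcript-frame row).  Bins are z-scored, segmented with
    ``pelt_mean`` at penalty ``2·ln n``, and a segment is stalled iff its
    raw mean exceeds both the gene's median raw bin value and its
    ``quantile`` empirical quantile.  Segment coordinates are clipped to the
    gene.  Genes shorter than ``min_bins`` bins or with constant signal
    yield no calls.
    """
    raw, b0 = track.gene_bins(gene.chrom, int(gene.start), int(gene.end))
    n = len(raw)
    if n < min_bins or raw.std() == 0:
        return pd.DataFrame(columns=STALL_COLS)
    z = scale_gene_signal(raw)
    penalty = 2.0 * math.log(n)
    cps = pelt_mean(z, penalty)
    bounds = [0] + cps + [n]
    med = np.median(raw)
    qval = np.quantile(raw, quantile)
    bw = track.bin_width
    out = []
    for s, t in zip(bounds[:-1], bounds[1:]):
        seg_mean = float(raw[s:t].mean())
        if seg_mean > med and seg_mean > qval:
            start = max(int(gene.start), (b0 + s) * bw)
            end = min(int(gene.end), (b0 + t) * bw)
            if end > start:
                out.append((gene.chrom, start, end, gene.name, seg_mean, source))
    return pd.DataFrame(out, columns=STALL_COLS)


def call_stalls(
    transcripts: pd.DataFrame,
    plus: StrandedBinnedTrack,
    minus: StrandedBinnedTrack | None = None,
    quantile: float = 0.90,
    source: str = "groseq",
) -> pd.DataFrame:
    """Stall segments for every transcript, sense-strand track per gene.

    For unstranded input (ChIP), pass the same track as ``plus`` with
    ``minus=None``: every gene is then scanned on that single track.
    Genes shorter than 4 bins are skipped with a logged count.
    """
    frames = []
    n_short = 0
    for gene in transcripts.itertuples(index=False):
        track = plus if (minus is None or gene.strand == "+") else minus
        raw, _ = track.gene_bins(gene.chrom, int(gene.start), int(gene.end))
        if len(raw) < 4:
            n_short += 1
            continue
        calls = call_stall_segments(gene, track, quantile=quantile, source=source)
        if len(calls):
            frames.append(calls)
    if n_short:
        logger.info("skipped %d genes shorter than 4 bins", n_short)
    if not frames:
        return pd.DataFrame(columns=STALL_COLS)
    return pd.concat(frames, ignore_index=True)


def merge_stalls(segments: pd.DataFrame, gap: int = 100) -> pd.DataFrame:
    """Merge stall calls across samples/sources at ``gap`` bp (default 100)."""
    return merge_intervals(segments, gap=gap)


def annotation_match_filter(detected: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Keep detected transcripts with a matching same-strand annotation.

    A detected transcript is kept iff some same-strand annotation satisfies
    all of: the annotation covers at least 5% of the detected length; at
    least 50% of that annotation lies inside the detected transcript; and
    the annotated and detected starts (TSS, strand-aware) differ by at most
    10 kb.
    """
    if len(detected) == 0:
        return detected.copy()
    keep = np.zeros(len(detected), dtype=bool)
    ann_by_key = {k: sub for k, sub in annotations.groupby(["chrom", "strand"], sort=False)}
    for i, det in enumerate(detected.itertuples(index=False)):
        sub = ann_by_key.get((det.chrom, det.strand))
        if sub is None:
            continue
        det_len = det.end - det.start
        det_tss = det.start if det.strand == "+" else det.end
        for ann in sub.itertuples(index=False):
            ov = min(det.end, ann.end) - max(det.start, ann.start)
            if ov <= 0:
                continue
            ann_tss = ann.start if ann.strand == "+" else ann.end
            if (
                ov >= 0.05 * det_len
                and ov >= 0.50 * (ann.end - ann.start)
                and abs(det_tss - ann_tss) <= 10_000
            ):
                keep[i] = True
                break
    return detected[keep].reset_index(drop=True)
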