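"""Width-based analyses and signal metaprofiles.

Links wide polymerase stalling sites to open chromatin (peak-width
comparisons, top-5%-widest co-occurrence), stratifies TSS signal by feature
overlap (R-loop-forming sequences, convergent transcription), and builds
length-normalized 100-bin gene metaprofiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import REGION_COLS, intersect_bp, merge_intervals, subtract_regions, windowed_overlap
from .stats import ShiftResult, fisher_or, wilcoxon_shift
from .track import StrandedBinnedTrack

logger = logging.getLogger(__name__)


def peak_width_by_overlap(
    peaks: pd.DataFrame,
    stalls: pd.DataFrame,
    score_min: float = 15.0,
    restrict_to: pd.DataFrame | None = None,
) -> dict:
    """Compare widths of peaks overlapping vs not overlapping stall sites.

    Peaks with score strictly above ``score_min`` are kept, optionally
    restricted to a zone (TSS / gene body / gene end), partitioned by
    any-overlap with stalls, and the two width samples compared with the
    rank-sum shift test.  With fewer than 2 peaks in a stratum the test is
    reported missing.
    """
    kept = peaks[pd.to_numeric(peaks["score"]) > score_min].reset_index(drop=True)
    if restrict_to is not None:
        kept = kept[windowed_overlap(kept, restrict_to, window=0)].reset_index(drop=True)
    flags = windowed_overlap(kept, stalls, window=0)
    widths = (kept["end"] - kept["start"]).to_numpy()
    over, non = widths[flags], widths[~flags]
    result: ShiftResult | None = None
    if len(over) >= 2 and len(non) >= 2:
        result = wilcoxon_shift(over, non)
    return {
        "widths_overlapping": over,
        "widths_non_overlapping": non,
        "test": result,
    }


def tss_regions(transcripts: pd.DataFrame, halfwidth: int = 1000) -> pd.DataFrame:
    """±halfwidth windows around annotated, strand-aware start coordinates."""
    tss = np.where(transcripts["strand"] == "+", transcripts["start"], transcripts["end"])
    out = pd.DataFrame(
        {
            "chrom": transcripts["chrom"].to_numpy(),
            "start": np.maximum(0, tss - halfwidth),
            "end": tss + halfwidth,
        }
    )
    for col in ("name", "strand"):
        if col in transcripts.columns:
            out[col] = transcripts[col].to_numpy()
    return out.sort_values(REGION_COLS, kind="mergesort").reset_index(drop=True)


def tss_stall_width_by_breakpoint(
    tss_set: pd.DataFrame,
    stalls: pd.DataFrame,
    r_breakp: pd.DataFrame,
    all_breakp: pd.DataFrame | None = None,
) -> dict:
    """Stall widths at breakpoint-bearing vs breakpoint-free TSS.

    Sample 1: widths of stall sites overlapping TSS windows that harbor an
    R-class breakpoint region; sample 2: widths of stalls overlapping TSS
    windows free of any breakpoint region (``all_breakp``, defaulting to
    ``r_breakp``).  A stall overlapping TSS of both classes contributes to
    both samples.
    """
    if all_breakp is None:
        all_breakp = r_breakp
    with_bp = tss_set[windowed_overlap(tss_set, r_breakp, window=0)]
    without_bp = tss_set[~windowed_overlap(tss_set, all_breakp, window=0)]
    w_with = _stall_widths_at(stalls, with_bp)
    w_without = _stall_widths_at(stalls, without_bp)
    result = None
    if len(w_with) >= 2 and len(w_without) >= 2:
        result = wilcoxon_shift(w_with, w_without)
    return {"widths_at_breakpoint_tss": w_with, "widths_at_clean_tss": w_without, "test": result}


def _stall_widths_at(stalls: pd.DataFrame, tss: pd.DataFrame) -> np.ndarray:
    if len(tss) == 0 or len(stalls) == 0:
        return np.array([], dtype=float)
    flags = windowed_overlap(stalls, tss, window=0)
    sub = stalls[flags]
    return (sub["end"] - sub["start"]).to_numpy(dtype=float)


def top_widest(regions: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """The widest ``fraction`` of regions (at least one); ties at the cut
    resolved by genomic order."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    df = regions.sort_values(REGION_COLS, kind="mergesort").reset_index(drop=True)
    widths = (df["end"] - df["start"]).to_numpy()
    k = max(1, int(np.ceil(len(df) * fraction)))
    order = np.argsort(-widths, kind="stable")
    return df.iloc[np.sort(order[:k])].reset_index(drop=True)


def top_widest_cooccurrence(
    stalls: pd.DataFrame, other_peaks: pd.DataFrame, fraction: float = 0.05
) -> dict:
    """Fisher's test for bp-level co-occurrence of the widest stall sites
    and the widest peaks.

    The contingency space is the union of all candidate regions; cells
    count base pairs covered by both wide sets, one, or neither.
    """
    wide_s = top_widest(stalls, fraction)
    wide_p = top_widest(other_peaks, fraction)
    universe = merge_intervals(pd.concat([stalls[REGION_COLS], other_peaks[REGION_COLS]]))
    total = int((universe["end"] - universe["start"]).sum())
    a = intersect_bp(wide_s, wide_p)
    s_bp = intersect_bp(wide_s, universe)
    p_bp = intersect_bp(wide_p, universe)
    b = s_bp - a
    c = p_bp - a
    d = total - a - b - c
    or_hat, p, ci = fisher_or(a, b, c, d)
    return {"table": (a, b, c, d), "odds_ratio": or_hat, "p": p, "ci": ci}


def tss_signal_stratified(
    track: StrandedBinnedTrack,
    tss_set: pd.DataFrame,
    strata: pd.DataFrame,
) -> dict:
    """Log2 TSS signal split by stratum overlap (e.g. RLFS+/- or convT+/-).

    Per-TSS signal is log2(1 + mean bin value over the window); the fold
    change of group medians is computed on the linear scale.  With an empty
    stratum a single group is returned and the test and fold are missing.
    """
    linear = np.array(
        [
            track.region_mean(r.chrom, int(r.start), int(r.end)) * track.bin_width
            for r in tss_set.itertuples(index=False)
        ]
    )
    log2sig = np.log2(1 + linear)
    flags = (
        windowed_overlap(tss_set, strata, window=0)
        if len(strata)
        else np.zeros(len(tss_set), dtype=bool)
    )
    pos, neg = log2sig[flags], log2sig[~flags]
    result = None
    fold = float("nan")
    if len(pos) >= 2 and len(neg) >= 2:
        result = wilcoxon_shift(pos, neg)
        med_neg = float(np.median(linear[~flags]))
        if med_neg > 0:
            fold = float(np.median(linear[flags])) / med_neg
    return {"log2_in_stratum": pos, "log2_outside": neg, "test": result, "median_fold": fold}


def rebin_profile(per_bp: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a per-bp signal vector into ``n_bins`` contiguous chunks.

    Returns (chunk masses, chunk per-bp densities).  Chunk boundaries are
    the integer grid closest to an equal split, so the masses partition the
    gene's total signal exactly.
    """
    n = len(per_bp)
    if n < n_bins:
        raise ValueError("region shorter than the number of bins")
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    masses = np.add.reduceat(per_bp, edges[:-1])
    lengths = np.diff(edges)
    return masses, masses / lengths


def metaprofile(
    track: StrandedBinnedTrack,
    genes: pd.DataFrame,
    n_bins: int = 100,
    min_rpkm: float | None = 0.5,
) -> np.ndarray:
    """Length-normalized mean signal profile over active genes.

    Each gene's per-bp signal is re-binned to ``n_bins`` equal-length bins
    (minus-strand genes reversed so bin 0 is the TSS), densities averaged
    over genes, and the profile scaled to sum to 1.  Genes shorter than
    ``n_bins`` bp (or below ``min_rpkm``) are dropped with a logged count.
    """
    sel = genes
    if min_rpkm is not None and "rpkm" in genes.columns:
        sel = genes[genes["rpkm"] > min_rpkm]
    profiles = []
    n_short = 0
    for gene in sel.itertuples(index=False):
        length = int(gene.end) - int(gene.start)
        if length < n_bins:
            n_short += 1
            continue
        per_bp = _per_bp_signal(track, gene.chrom, int(gene.start), int(gene.end))
        _, density = rebin_profile(per_bp, n_bins)
        if gene.strand == "-":
            density = density[::-1]
        profiles.append(density)
    if n_short:
        logger.info("dropped %d genes shorter than %d bp", n_short, n_bins)
    if not profiles:
        raise ValueError("no genes usable for the metaprofile")
    mean_profile = np.mean(profiles, axis=0)
    total = mean_profile.sum()
    return mean_profile / total if total > 0 else mean_profile


def _per_bp_signal(track: StrandedBinnedTrack, chrom: str, start: int, end: int) -> np.ndarray:
    bw = track.bin_width
    vals, b0 = track.gene_bins(chrom, start, end)
    lens = np.array([track._bin_len(chrom, b0 + i) for i in range(len(vals))])
    per_bp = np.repeat(vals / lens, lens)
    offset = start - b0 * bw
    return per_bp[offset:offset + (end - start)]


__all__ = [
    "peak_width_by_overlap",
    "tss_regions",
    "tss_stall_width_by_breakpoint",
    "top_widest",
    "top_widest_cooccurrence",
    "tss_signal_stratified",
    "rebin_profile",
    "metaprofile",
    "subtract_regions",
]
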