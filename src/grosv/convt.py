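"""Convergent-transcription (convT) region detection and quantification.

A convT region is a locus transcribed on both strands: here, a maximal run
of base pairs covered by both a plus- and a minus-strand transcript, kept
when at least 100 bp long.  The convT level of a region is the weaker
strand's size-normalized signal (min over strands of signal mass per bp).
Short (<15 kb) transcripts with divergent partners or enhancer-mark overlap
are flagged as enhancer-RNA (eRNA) candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import REGION_COLS, merge_intervals, windowed_overlap
from .track import StrandedBinnedTrack


def detect_convt(transcripts: pd.DataFrame, min_overlap: int = 100) -> pd.DataFrame:
    """Maximal opposite-strand overlap runs of length >= ``min_overlap``.

    Equivalent to intersecting the unions of plus- and minus-strand
    transcript footprints and keeping runs of sufficient length; overlapping
    emissions are merged at gap 0 by construction.
    """
    if "strand" not in transcripts.columns:
        raise ValueError("transcripts must carry a strand column")
    plus = merge_intervals(transcripts[transcripts["strand"] == "+"])
    minus = merge_intervals(transcripts[transcripts["strand"] == "-"])
    out: list[tuple[str, int, int]] = []
    for chrom, sub_p in plus.groupby("chrom", sort=False):
        sub_m = minus[minus["chrom"] == chrom]
        if len(sub_m) == 0:
            continue
        sp, ep = sub_p["start"].to_numpy(), sub_p["end"].to_numpy()
        sm, em = sub_m["start"].to_numpy(), sub_m["end"].to_numpy()
        i = j = 0
        while i < len(sp) and j < len(sm):
            lo = max(sp[i], sm[j])
            hi = min(ep[i], em[j])
            if hi - lo >= min_overlap:
                out.append((chrom, int(lo), int(hi)))
            if ep[i] <= em[j]:
                i += 1
            else:
                j += 1
    return pd.DataFrame(out, columns=REGION_COLS)


def combine_convt(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of convT calls from several samples (merge at gap 0)."""
    if not tracks:
        return pd.DataFrame(columns=REGION_COLS)
    return merge_intervals(pd.concat(tracks, ignore_index=True), gap=0)


def quantify_convt(
    region, plus_track: StrandedBinnedTrack, minus_track: StrandedBinnedTrack
) -> float:
    """convT level: min over strands of signal mass per bp over the region."""
    chrom, start, end = region.chrom, int(region.start), int(region.end)
    p = plus_track.region_mass(chrom, start, end)
    m = minus_track.region_mass(chrom, start, end)
    return min(p, m) / (end - start)


def quantify_convt_regions(
    regions: pd.DataFrame,
    plus_track: StrandedBinnedTrack,
    minus_track: StrandedBinnedTrack,
) -> pd.DataFrame:
    """Attach a ``level`` column (weaker-strand signal per bp) to regions."""
    out = regions.copy()
    out["level"] = [
        quantify_convt(r, plus_track, minus_track) for r in regions.itertuples(index=False)
    ]
    return out


def antisense_quartiles(regions: pd.DataFrame, level_col: str = "level") -> pd.DataFrame:
    """Label regions Q1..Q4 by the weaker-strand (antisense) signal level.

    Regions are ranked by level with ties broken by genomic order (stable),
    then split into four rank quartiles of as-equal-as-possible size.
    """
    if len(regions) < 4:
        raise ValueError(f"need at least 4 regions, got {len(regions)}")
    out = regions.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    order = np.argsort(out[level_col].to_numpy(), kind="stable")
    n = len(out)
    labels = np.empty(n, dtype=object)
    for rank, idx in enumerate(order):
        labels[idx] = f"Q{min(3, 4 * rank // n) + 1}"
    out["quartile"] = labels
    return out


def call_ernas(
    transcripts: pd.DataFrame,
    enhancer_marks: pd.DataFrame | None = None,
    max_length: int = 15_000,
    divergent_window: int = 1000,
) -> pd.DataFrame:
    """Enhancer-RNA candidates: short transcripts that are bidirectional or
    co-localize with enhancer marks.

    Kept iff length < ``max_length`` and (an opposite-strand transcript's
    start (TSS) lies within ``divergent_window`` bp of this transcript's
    start, or the transcript overlaps ``enhancer_marks``).
    """
    if len(transcripts) == 0:
        return transcripts.copy()
    t = transcripts.reset_index(drop=True)
    length_ok = (t["end"] - t["start"]) < max_length
    tss = np.where(t["strand"] == "+", t["start"], t["end"])
    bidirectional = np.zeros(len(t), dtype=bool)
    for chrom, sub in t.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for strand, other in (("+", "-"), ("-", "+")):
            mine = idx[sub["strand"].to_numpy() == strand]
            theirs = np.sort(tss[idx[sub["strand"].to_numpy() == other]])
            if len(theirs) == 0:
                continue
            for i in mine:
                j = np.searchsorted(theirs, tss[i])
                near = []
                if j < len(theirs):
                    near.append(abs(theirs[j] - tss[i]))
                if j > 0:
                    near.append(abs(theirs[j - 1] - tss[i]))
                if near and min(near) <= divergent_window:
                    bidirectional[i] = True
    marked = np.zeros(len(t), dtype=bool)
    if enhancer_marks is not None and len(enhancer_marks):
        marked = windowed_overlap(t, enhancer_marks, window=0)
    return t[length_ok & (bidirectional | marked)].reset_index(drop=True)
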