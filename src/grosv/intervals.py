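"""Interval algebra on half-open genomic coordinates.

Region sets are plain :class:`pandas.DataFrame` objects with at least the
columns ``chrom``, ``start``, ``end`` (0-based, half-open, BED convention);
extra columns (``strand``, ``score``, ...) ride along untouched unless an
operation has to drop them.  All operations are strand-agnostic unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REGION_COLS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def as_regions(records: Iterable[tuple], columns: list[str] | None = None) -> pd.DataFrame:
    """Build a region frame from (chrom, start, end, ...) tuples."""
    cols = columns or REGION_COLS
    df = pd.DataFrame.from_records(list(records), columns=cols)
    return sort_regions(df)


def empty_regions(extra_cols: list[str] | None = None) -> pd.DataFrame:
    return pd.DataFrame(columns=REGION_COLS + (extra_cols or []))


def validate_regions(df: pd.DataFrame, chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Raise ValueError on malformed coordinates or out-of-bounds records."""
    missing = [c for c in REGION_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"region frame missing columns {missing}")
    if len(df) == 0:
        return
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
        raise ValueError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    if chrom_sizes is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            over = sub[sub["end"] > chrom_sizes[chrom]]
            if len(over):
                r = over.iloc[0]
                raise ValueError(
                    f"record {r['chrom']}:{r['start']}-{r['end']} exceeds "
                    f"chromosome length {chrom_sizes[chrom]}"
                )


def sort_regions(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Strand-agnostic union; intervals separated by ``<= gap`` bp are joined.

    Output is sorted and pairwise separated by more than ``gap``.  Only the
    coordinate columns survive.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    if len(df) == 0:
        return empty_regions()
    out: list[tuple[str, int, int]] = []
    for chrom, sub in sort_regions(df[REGION_COLS]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=REGION_COLS)


def windowed_overlap(a: pd.DataFrame, b: pd.DataFrame, window: int = 0) -> np.ndarray:
    """Flag each interval of ``a`` that lies within ``window`` bp of some ``b``.

    An interval of ``a`` is flagged when its distance to some ``b`` interval
    is at most ``window`` bp, where touching or overlapping intervals have
    distance 0 (so ``window=0`` flags touching intervals too).  Returns a
    boolean array aligned with ``a``'s rows.
    """
    flags = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return flags
    merged = merge_intervals(b)
    by_chrom = {c: (sub["start"].to_numpy(), sub["end"].to_numpy())
                for c, sub in merged.groupby("chrom", sort=False)}
    chroms = a["chrom"].to_numpy()
    starts = a["start"].to_numpy()
    ends = a["end"].to_numpy()
    for i in range(len(a)):
        hit = by_chrom.get(chroms[i])
        if hit is None:
            continue
        bs, be = hit
        lo = starts[i] - window
        hi = ends[i] + window
        # merged b is disjoint & sorted: only the last interval starting
        # at or before hi can be within distance of [lo, hi]
        j = np.searchsorted(bs, hi, side="right") - 1
        flags[i] = j >= 0 and be[j] >= lo
    return flags


def intersects(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Flag each ``a`` interval sharing at least 1 bp with some ``b``
    (touching intervals do not count)."""
    return windowed_overlap(a, b, window=-1)


def coverage_fraction(region: GenomicInterval, features: pd.DataFrame) -> float:
    """Fraction of ``region`` covered by the union of ``features``, in [0, 1]."""
    if len(region) == 0:
        raise ValueError("zero-length region")
    covered = intersect_bp(
        pd.DataFrame([[region.chrom, region.start, region.end]], columns=REGION_COLS),
        features,
    )
    return covered / len(region)


def intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Base pairs in the intersection of the unions of two region sets."""
    if len(a) == 0 or len(b) == 0:
        return 0
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    for chrom, sub_a in ma.groupby("chrom", sort=False):
        sub_b = mb[mb["chrom"] == chrom]
        if len(sub_b) == 0:
            continue
        sa, ea = sub_a["start"].to_numpy(), sub_a["end"].to_numpy()
        sb, eb = sub_b["start"].to_numpy(), sub_b["end"].to_numpy()
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if hi > lo:
                total += int(hi - lo)
            if ea[i] <= eb[j]:
                i += 1
            else:
                j += 1
    return total


def subtract_regions(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pieces of the union of ``a`` not covered by the union of ``b``."""
    ma = merge_intervals(a)
    if len(ma) == 0:
        return empty_regions()
    mb = merge_intervals(b)
    out: list[tuple[str, int, int]] = []
    for chrom, sub_a in ma.groupby("chrom", sort=False):
        sub_b = mb[mb["chrom"] == chrom]
        sb = sub_b["start"].to_numpy()
        eb = sub_b["end"].to_numpy()
        for s, e in zip(sub_a["start"], sub_a["end"]):
            cur = int(s)
            for bs, be in zip(sb, eb):
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    out.append((chrom, cur, int(bs)))
                cur = max(cur, int(be))
                if cur >= e:
                    break
            if cur < e:
                out.append((chrom, cur, int(e)))
    return pd.DataFrame(out, columns=REGION_COLS)


def total_bp(df: pd.DataFrame) -> int:
    """Base pairs in the union of a region set."""
    m = merge_intervals(df)
    if len(m) == 0:
        return 0
    return int((m["end"] - m["start"]).sum())


def tile_windows(universe: pd.DataFrame, width: int = 1000, min_width: int | None = None) -> pd.DataFrame:
    """Tile the union of ``universe`` with non-overlapping windows.

    Windows are clipped at the end of each universe piece; clipped windows
    shorter than ``min_width`` (default ``width // 2``) are dropped.
    """
    if min_width is None:
        min_width = width // 2
    merged = merge_intervals(universe)
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in merged.itertuples(index=False):
        pos = int(s)
        while pos < e:
            stop = min(pos + width, int(e))
            if stop - pos >= min_width:
                out.append((chrom, pos, stop))
            pos += width
    return pd.DataFrame(out, columns=REGION_COLS)
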