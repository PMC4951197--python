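"""Fixed-width binned, stranded signal tracks.

A :class:`StrandedBinnedTrack` holds one strand of genome-wide signal at a
fixed bin width (50 bp by default), per chromosome, as dense numpy arrays.
Signal read from bedGraph is distributed to bins mass-conservingly by
base-pair overlap, so a round-trip through the reader preserves the total
read mass.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np


class StrandedBinnedTrack:
    """Per-chromosome fixed-width bin values for one strand.

    Bin ``i`` of a chromosome covers ``[i*bin_width, min((i+1)*bin_width, L))``.
    Values are non-negative; minus-strand bedGraph files that encode signal as
    negative values (browser convention) are rectified on read.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        bin_width: int = 50,
        strand: str = "+",
        values: Mapping[str, np.ndarray] | None = None,
    ):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {strand!r}")
        self.chrom_sizes = dict(chrom_sizes)
        self.bin_width = bin_width
        self.strand = strand
        self.values: dict[str, np.ndarray] = {}
        for chrom, length in self.chrom_sizes.items():
            n = -(-length // bin_width)  # ceil
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=float)
                if len(arr) != n:
                    raise ValueError(f"{chrom}: expected {n} bins, got {len(arr)}")
                if (arr < 0).any():
                    raise ValueError(f"{chrom}: negative bin values")
                self.values[chrom] = arr
            else:
                self.values[chrom] = np.zeros(n)
        self.n_skipped_records = 0

    @classmethod
    def from_bedgraph(
        cls,
        path: str,
        chrom_sizes: Mapping[str, int],
        bin_width: int = 50,
        strand: str = "+",
    ) -> "StrandedBinnedTrack":
        """Read a 4-column bedGraph, distributing each record's signal mass to
        bins proportionally to base-pair overlap.

        Records on chromosomes absent from ``chrom_sizes`` are skipped (their
        count kept in ``n_skipped_records``); a record extending beyond its
        chromosome is an error.
        """
        track = cls(chrom_sizes, bin_width=bin_width, strand=strand)
        bw = bin_width
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"{path}:{line_no}: expected 4 columns")
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                if chrom not in track.chrom_sizes:
                    track.n_skipped_records += 1
                    continue
                if e > track.chrom_sizes[chrom]:
                    raise ValueError(
                        f"{path}:{line_no}: record {chrom}:{s}-{e} exceeds "
                        f"chromosome length {track.chrom_sizes[chrom]}"
                    )
                if s >= e:
                    raise ValueError(f"{path}:{line_no}: invalid interval {s}-{e}")
                v = abs(v)  # minus-strand browser tracks store negatives
                arr = track.values[chrom]
                per_bp = v / (e - s)
                b0, b1 = s // bw, (e - 1) // bw
                if b0 == b1:
                    arr[b0] += v
                else:
                    arr[b0] += per_bp * ((b0 + 1) * bw - s)
                    arr[b1] += per_bp * (e - b1 * bw)
                    if b1 > b0 + 1:
                        arr[b0 + 1:b1] += per_bp * bw
        if track.n_skipped_records:
            warnings.warn(
                f"{path}: skipped {track.n_skipped_records} records on unknown chromosomes"
            )
        return track

    def to_bedgraph(self, path: str) -> None:
        """Write non-zero bins as bedGraph records."""
        with open(path, "w") as fh:
            for chrom in self.chrom_sizes:
                arr = self.values[chrom]
                length = self.chrom_sizes[chrom]
                (nz,) = np.nonzero(arr)
                for i in nz:
                    s = int(i) * self.bin_width
                    e = min(s + self.bin_width, length)
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[i]:.12g}\n")

    def total_mass(self) -> float:
        return float(sum(arr.sum() for arr in self.values.values()))

    def region_mass(self, chrom: str, start: int, end: int) -> float:
        """Signal mass over ``[start, end)``, fractional at partial bins
        (mass assumed uniform within a bin)."""
        if chrom not in self.values:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= start < end <= self.chrom_sizes[chrom]:
            raise ValueError(f"region {chrom}:{start}-{end} outside track")
        bw = self.bin_width
        arr = self.values[chrom]
        b0, b1 = start // bw, (end - 1) // bw
        if b0 == b1:
            return float(arr[b0] * (end - start) / self._bin_len(chrom, b0))
        mass = arr[b0] * ((b0 + 1) * bw - start) / self._bin_len(chrom, b0)
        mass += arr[b1] * (end - b1 * bw) / self._bin_len(chrom, b1)
        mass += arr[b0 + 1:b1].sum()
        return float(mass)

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal per bp over the region."""
        return self.region_mass(chrom, start, end) / (end - start)

    def gene_bins(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, int]:
        """Raw values of the genome-aligned bins overlapping ``[start, end)``.

        Returns ``(values, first_bin_index)`` so callers can map bin indices
        back to genomic coordinates.
        """
        if chrom not in self.values:
            raise KeyError(f"unknown chromosome {chrom!r}")
        bw = self.bin_width
        b0, b1 = start // bw, (end - 1) // bw
        return self.values[chrom][b0:b1 + 1].copy(), int(b0)

    def _bin_len(self, chrom: str, i: int) -> int:
        return min((i + 1) * self.bin_width, self.chrom_sizes[chrom]) - i * self.bin_width
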