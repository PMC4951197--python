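"""Pipeline configuration.

Every fixed analysis parameter lives here so that the interval, stalling,
breakpoint and statistics modules share one source of truth.  Defaults follow
the published analysis protocol (50-bp signal bins, 100-bp convergent-
transcription overlap, 1-kb stitching and overlap windows, 90%/80% stalling
quantiles, 0.003 motif p-value, 1000 resamples, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml


@dataclass
class Config:
    """Fixed analysis parameters with protocol defaults.

    Attributes
    ----------
    convt_min_overlap : int
        Minimum opposite-strand transcript overlap (bp) to call a
        convergent-transcription region.
    stall_bin : int
        Signal bin width (bp) for change-point analysis.
    stall_quantile_groseq, stall_quantile_chip : float
        Per-gene raw-signal quantile a segment mean must exceed to be
        reported as stalled (nascent-transcription vs ChIP input).
    stall_merge_gap : int
        Gap (bp) at which stall calls from different samples are merged.
    stitch_distance : int
        Maximum distance (bp) between successive breakpoint ends chained
        into one stitched region.
    rss_flank : int
        Flank (bp) added on each side of a breakpoint before motif scanning
        (10 bp flanks give the 21-bp scan window).
    rss_pvalue : float
        Motif-match p-value cutoff for RSS-positive classification.
    overlap_window : int
        Window (bp) for breakpoint-region / feature overlap queries.
    tss_halfwidth : int
        Half-width (bp) of TSS windows.
    top_width_fraction : float
        Fraction of widest regions taken in width co-occurrence analyses.
    n_resamples : int
        Resamples for the empirical overlap null.
    dnase_score_min : float
        Open-chromatin peaks kept only when score is strictly above this.
    erna_max_length : int
        Maximum transcript length (bp) for enhancer-RNA candidates.
    hic_bin : int
        Contact-matrix resolution (bp).
    active_rpkm_min : float
        Minimum RPKM for a gene to count as active in metaprofiles.
    metaprofile_bins : int
        Number of length-normalized bins in gene metaprofiles.
    seed : int
        Seed for every stochastic step.
    """

    convt_min_overlap: int = 100
    stall_bin: int = 50
    stall_quantile_groseq: float = 0.90
    stall_quantile_chip: float = 0.80
    stall_merge_gap: int = 100
    stitch_distance: int = 1000
    rss_flank: int = 10
    rss_pvalue: float = 0.003
    overlap_window: int = 1000
    tss_halfwidth: int = 1000
    top_width_fraction: float = 0.05
    n_resamples: int = 1000
    dnase_score_min: float = 15.0
    erna_max_length: int = 15_000
    hic_bin: int = 50_000
    active_rpkm_min: float = 0.5
    metaprofile_bins: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "seed":
                continue
            if v <= 0:
                raise ValueError(f"Config.{f.name} must be positive, got {v!r}")
        for name in ("stall_quantile_groseq", "stall_quantile_chip", "top_width_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"Config.{name} must be in (0, 1), got {v!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"Unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)
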