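"""Breakpoint classification, stitching and feature-overlap analyses.

Breakpoints are single coordinates (structural-variant ends).  Each is
classified for a recombination-signal-sequence (RSS)-like motif by scanning
a 21-bp window (10-bp flanks) on both strands with a position weight matrix;
match p-values are exact, computed by dynamic programming over the
integer-scaled log-odds score distribution under the background (per-match
semantics, no multiple-position correction).  Breakpoint ends within 1 kb
are stitched into regions whose member count defines recurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import windowed_overlap

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

STITCH_COLS = ["chrom", "start", "end", "n_breakpoints", "rss_class"]


@dataclass
class PWM:
    """Position weight matrix with 0-order background.

    ``probs`` is a (width, 4) array over A,C,G,T; rows must sum to 1.
    Log-odds scores use a small background-weighted pseudocount so that
    zero-probability cells stay finite.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"
    pseudo: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1 within 1e-9")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background,
            name=self.name + "_rc",
            pseudo=self.pseudo,
        )

    def _int_scores(self, scale: int = 1000) -> np.ndarray:
        p = (1 - self.pseudo) * self.probs + self.pseudo * self.background
        lod = np.log2(p / self.background)
        return np.round(lod * scale).astype(int)

    def score_table(self, scale: int = 1000) -> dict[int, float]:
        """Exact distribution of the integer-scaled window score under the
        background (independent positions)."""
        ints = self._int_scores(scale)
        dist: dict[int, float] = {0: 1.0}
        for row in ints:
            new: dict[int, float] = {}
            for s, pr in dist.items():
                for b in range(4):
                    key = s + int(row[b])
                    new[key] = new.get(key, 0.0) + pr * self.background[b]
            dist = new
        return dist

    def pvalue_lookup(self, scale: int = 1000):
        """Return ``(int_matrix, pvalue_fn)``: exact P(score >= s) under the
        background, over the integer score grid used for scanning."""
        ints = self._int_scores(scale)
        dist = self.score_table(scale)
        scores = np.array(sorted(dist))
        tail = np.cumsum([dist[s] for s in scores][::-1])[::-1]

        def pvalue(s: int) -> float:
            i = np.searchsorted(scores, s, side="left")
            return float(tail[i]) if i < len(scores) else 0.0

        return ints, pvalue


def scan_window(seq: str, pwm: PWM, scale: int = 1000) -> float:
    """Best (minimum) exact per-position match p-value over both strands of
    ``seq``.  Returns nan when the window is shorter than the motif or
    contains non-ACGT characters."""
    seq = seq.upper()
    w = pwm.width
    if len(seq) < w or any(c not in BASES for c in seq):
        return float("nan")
    idx = np.array([BASES.index(c) for c in seq])
    best = np.inf
    for mat in (pwm, pwm.reverse_complement()):
        ints, pvalue = _cached_lookup(mat, scale)
        for off in range(len(seq) - w + 1):
            s = int(ints[np.arange(w), idx[off:off + w]].sum())
            best = min(best, pvalue(s))
    return float(best)


_LOOKUP_CACHE: dict[tuple, tuple] = {}


def _cached_lookup(pwm: PWM, scale: int):
    key = (pwm.probs.tobytes(), pwm.background.tobytes(), pwm.pseudo, scale)
    if key not in _LOOKUP_CACHE:
        _LOOKUP_CACHE[key] = pwm.pvalue_lookup(scale)
    return _LOOKUP_CACHE[key]


def classify_rss(
    breakpoints: pd.DataFrame,
    genome,
    pwm: PWM,
    flank: int = 10,
    p_cut: float = 0.003,
) -> pd.DataFrame:
    """Assign rss_status R/NR/NA per breakpoint by motif scanning.

    ``genome`` is a mapping of chromosome name to sequence (a pyfaidx Fasta
    or a plain dict of strings).  The breakpoint is extended by ``flank`` bp
    on both sides (21-bp window at the default), both strands are scanned,
    and the breakpoint is R iff the best match p-value is <= ``p_cut``.
    Windows with missing sequence or non-ACGT characters are NA.
    """
    out = breakpoints.copy().reset_index(drop=True)
    status = []
    n_missing = 0
    for bp in out.itertuples(index=False):
        try:
            ref = genome[bp.chrom]
        except KeyError:
            ref = None
        if ref is None:
            n_missing += 1
            status.append("NA")
            continue
        lo = max(0, bp.pos - flank)
        hi = min(len(ref), bp.pos + flank + 1)
        seq = str(ref[lo:hi])
        p = scan_window(seq, pwm)
        if np.isnan(p):
            status.append("NA")
        else:
            status.append("R" if p <= p_cut else "NR")
    if n_missing:
        warnings.warn(f"{n_missing} breakpoints on chromosomes missing from the genome")
    out["rss_status"] = status
    return out


def stitch(breakpoints: pd.DataFrame, distance: int = 1000) -> pd.DataFrame:
    """Single-linkage stitch of breakpoint ends at <= ``distance`` bp.

    Successive positions on a chromosome differing by at most ``distance``
    chain into one region.  The region interval spans the member positions
    (half-open, min..max+1); ``n_breakpoints`` counts members and sums to
    the input count; rss_class is R if any member is R, else NR if any NR,
    else NA.
    """
    rows = []
    df = breakpoints.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, sub in df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        rss = sub["rss_status"].to_numpy() if "rss_status" in sub else np.array(["NA"] * len(sub))
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > distance:
                members = rss[start:i]
                if "R" in members:
                    cls = "R"
                elif "NR" in members:
                    cls = "NR"
                else:
                    cls = "NA"
                rows.append((chrom, int(pos[start]), int(pos[i - 1]) + 1, i - start, cls))
                start = i
    return pd.DataFrame(rows, columns=STITCH_COLS)


def recurrence_bins(regions: pd.DataFrame, cutoffs: tuple[int, ...] = (1, 2, 4)) -> pd.DataFrame:
    """Label each stitched region by the highest cutoff its count exceeds.

    With the default cutoffs a region of 1 breakpoint is the non-recurrent
    class "1"; larger counts get ">1", ">2" or ">4".
    """
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be ascending")
    out = regions.copy()
    labels = []
    for n in out["n_breakpoints"]:
        passed = [c for c in cutoffs if n > c]
        labels.append(f">{passed[-1]}" if passed else str(cutoffs[0]))
    out["recurrence_bin"] = labels
    return out


def breakpoint_feature_overlap(
    regions: pd.DataFrame,
    features: pd.DataFrame,
    window: int = 1000,
    genes: pd.DataFrame | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of breakpoint regions within ``window`` bp of a feature.

    When ``genes`` is given the analysis is intragenic: regions are first
    restricted to those overlapping a gene body.  Returns the fraction and
    the per-region flags (aligned with the possibly restricted frame, which
    callers can rebuild with the same filter).
    """
    if len(regions) == 0:
        raise ValueError("empty breakpoint region set")
    if genes is not None:
        keep = windowed_overlap(regions, genes, window=0)
        regions = regions[keep].reset_index(drop=True)
        if len(regions) == 0:
            raise ValueError("no breakpoint regions inside gene bodies")
    flags = windowed_overlap(regions, features, window=window)
    return float(flags.mean()), flags


def expression_binned_overlap(
    regions: pd.DataFrame,
    transcripts: pd.DataFrame,
    features: pd.DataFrame,
    window: int = 1000,
    rpkm_col: str = "rpkm",
) -> pd.DataFrame:
    """Feature-overlap fraction of regions stratified by host-gene expression.

    Genes are split into rank quartiles of maximum RPKM (Q1 lowest); each
    quartile's fraction is computed over the regions overlapping that
    quartile's gene bodies.
    """
    t = transcripts.reset_index(drop=True)
    order = np.argsort(t[rpkm_col].to_numpy(), kind="stable")
    n = len(t)
    qlab = np.empty(n, dtype=object)
    for rank, idx in enumerate(order):
        qlab[idx] = f"Q{min(3, 4 * rank // n) + 1}"
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        genes_q = t[qlab == q]
        in_q = windowed_overlap(regions, genes_q, window=0)
        sub = regions[in_q]
        if len(sub) == 0:
            rows.append((q, np.nan, 0))
        else:
            frac, _ = breakpoint_feature_overlap(sub.reset_index(drop=True), features, window)
            rows.append((q, frac, len(sub)))
    return pd.DataFrame(rows, columns=["quartile", "fraction", "n_regions"])


def cooccurrence(
    regions: pd.DataFrame,
    convt: pd.DataFrame,
    stalls: pd.DataFrame,
    window: int = 1000,
) -> dict[str, int]:
    """2x2 convT-flag x stall-flag table over breakpoint regions."""
    fc = windowed_overlap(regions, convt, window=window)
    fs = windowed_overlap(regions, stalls, window=window)
    return {
        "both": int((fc & fs).sum()),
        "convt_only": int((fc & ~fs).sum()),
        "stall_only": int((~fc & fs).sum()),
        "neither": int((~fc & ~fs).sum()),
        "either": int((fc | fs).sum()),
    }
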