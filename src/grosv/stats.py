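"""Shared statistical engine: enrichment tests, rank tests, resampling nulls.

Analytic tests (exact binomial, hypergeometric, Fisher, Wilcoxon rank-sum)
ride on scipy; the empirical null re-places query regions uniformly within a
genomic universe, preserving region sizes, and compares the observed feature
overlap against 1000 resamples with a z-score and a Davison–Hinkley
empirical p-value (the +1 estimator, so p is never exactly zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import intersects, merge_intervals, tile_windows, windowed_overlap


@dataclass
class EnrichmentResult:
    """Observed/expected overlap with analytic and empirical significance."""

    k: int
    n: int
    p0: float
    p_binomial: float
    p_hypergeom: float | None = None
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None
    p_empirical: float | None = None
    z: float | None = None
    n_resamples: int | None = None
    null_skewness: float | None = None


def binomial_enrichment(
    k: int,
    n: int,
    feature: pd.DataFrame,
    universe: pd.DataFrame,
    window: int = 1000,
) -> EnrichmentResult:
    """One-sided exact binomial enrichment of ``k`` successes in ``n`` trials.

    The success probability p0 is the fraction of non-overlapping ``window``-
    bp tiles of the universe (clipped tiles shorter than half a window are
    dropped) that share at least 1 bp with the feature.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    tiles = tile_windows(universe, width=window)
    hits = intersects(tiles, feature)
    p0 = float(hits.mean()) if len(tiles) else 0.0
    if p0 == 0.0 and k > 0:
        warnings.warn("background probability is 0 with k > 0; p-value degenerate")
        p = float(np.nextafter(0.0, 1.0))
    elif k == 0:
        p = 1.0
    else:
        p = float(sps.binom.sf(k - 1, n, p0))
    return EnrichmentResult(k=k, n=n, p0=p0, p_binomial=p)


def hypergeom_enrichment(
    sample_success: int, sample_size: int, pop_success: int, pop_size: int
) -> float:
    """Upper-tail exact hypergeometric p for >= observed successes."""
    if not (
        0 <= sample_success <= sample_size <= pop_size
        and sample_success <= pop_success <= pop_size
    ):
        raise ValueError("inconsistent hypergeometric counts")
    if sample_success == 0:
        return 1.0
    return float(sps.hypergeom.sf(sample_success - 1, pop_size, pop_success, sample_size))


def fisher_or(a: int, b: int, c: int, d: int):
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p_two_sided, (ci_low, ci_high))``.  The point
    estimate is the sample odds ratio ad/bc; the CI is the normal
    approximation on the log odds ratio with Haldane's 0.5 correction
    applied when any cell is zero.  When a full row or column is zero the
    odds ratio is undefined and NaN is returned for it and the CI.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), float(p), (float("nan"), float("nan"))
    if b * c == 0 and a * d == 0:
        or_hat = float("nan")
    elif b * c == 0:
        or_hat = float("inf")
    else:
        or_hat = (a * d) / (b * c)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if min(a, b, c, d) == 0 else (a, b, c, d)
    )
    log_or = np.log((aa * dd) / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (float(np.exp(log_or - 1.959964 * se)), float(np.exp(log_or + 1.959964 * se)))
    return or_hat, float(p), ci


@dataclass
class ShiftResult:
    """Rank-sum comparison of two samples with a location-shift estimate."""

    p: float
    hl_shift: float
    ci: tuple[float, float]
    median_x: float
    median_y: float
    fold_change: float  # median(x) / median(y); NaN when median(y) == 0


def wilcoxon_shift(x, y, exact_max: int = 20) -> ShiftResult:
    """Two-sided Wilcoxon rank-sum test with a Hodges–Lehmann shift.

    The p-value is exact when n+m <= ``exact_max`` (and no ties force the
    asymptotic path), otherwise a normal approximation with continuity
    correction.  The shift estimate is the median of all pairwise
    differences x_i - y_j; its 95% CI takes the order statistics of the
    pairwise differences at the normal-approximation ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 values")
    method = "exact" if nx + ny <= exact_max else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    total = nx * ny
    se = np.sqrt(nx * ny * (nx + ny + 1) / 12.0)
    k = int(np.floor(total / 2.0 - 1.959964 * se))
    k = max(k, 0)
    ci = (float(diffs[k]), float(diffs[total - k - 1]))
    mx, my = float(np.median(x)), float(np.median(y))
    fold = mx / my if my != 0 else float("nan")
    return ShiftResult(
        p=float(res.pvalue), hl_shift=hl, ci=ci, median_x=mx, median_y=my, fold_change=fold
    )


def sampling_null(
    regions: pd.DataFrame,
    universe: pd.DataFrame,
    feature: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
    window: int = 0,
) -> EnrichmentResult:
    """Empirical overlap null by re-placing regions within the universe.

    Each resample gives every query region a uniform random position inside
    a universe piece large enough to host it (sizes preserved, mutual
    overlap allowed), then measures the fraction of regions within
    ``window`` bp of the feature.  p_empirical = (1 + #resamples >= observed)
    / (n_resamples + 1); z standardizes the observed fraction against the
    null; the null's skewness is reported as a normality diagnostic.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    observed = float(windowed_overlap(regions, feature, window=window).mean())

    pieces = merge_intervals(universe)
    chrom_order = {c: i for i, c in enumerate(pieces["chrom"].unique())}
    # global coordinates: lay chromosomes end to end so a single sorted
    # feature array serves all placements
    offsets: dict[str, int] = {}
    cursor = 0
    for chrom in chrom_order:
        offsets[chrom] = cursor
        sub = pieces[pieces["chrom"] == chrom]
        cursor += int(sub["end"].max()) + window + 1  # guard gap: windows never span chroms
    piece_start = (pieces["start"] + pieces["chrom"].map(offsets)).to_numpy()
    piece_len = (pieces["end"] - pieces["start"]).to_numpy()

    mf = merge_intervals(feature)
    mf = mf[mf["chrom"].isin(offsets)].copy()
    mf["gstart"] = mf["start"] + mf["chrom"].map(offsets)
    mf["gend"] = mf["end"] + mf["chrom"].map(offsets)
    mf = mf.sort_values("gstart")
    f_start = mf["gstart"].to_numpy()
    f_end = mf["gend"].to_numpy()

    sizes = (regions["end"] - regions["start"]).to_numpy()
    rng = np.random.default_rng(seed)
    hit_counts = np.zeros(n_resamples, dtype=int)
    for size in np.unique(sizes):
        n_of_size = int((sizes == size).sum())
        room = piece_len - size + 1
        ok = room > 0
        if not ok.any():
            raise ValueError(f"no universe piece can host a region of {size} bp")
        weights = np.where(ok, room, 0).astype(float)
        weights /= weights.sum()
        total = n_of_size * n_resamples
        picks = rng.choice(len(piece_len), size=total, p=weights)
        starts = piece_start[picks] + rng.integers(0, room[picks], size=total)
        ends = starts + size
        if len(f_start) == 0:
            hits = np.zeros(total, dtype=bool)
        else:
            j = np.searchsorted(f_start, ends + window, side="right") - 1
            hits = (j >= 0) & (f_end[np.maximum(j, 0)] >= starts - window)
        hit_counts += hits.reshape(n_of_size, n_resamples).sum(axis=0)
    null = hit_counts / len(regions)
    p_emp = float((1 + (null >= observed - 1e-12).sum()) / (n_resamples + 1))
    sd = float(null.std(ddof=1))
    z = float((observed - null.mean()) / sd) if sd > 0 else float("nan")
    return EnrichmentResult(
        k=int(round(observed * len(regions))),
        n=len(regions),
        p0=float(null.mean()),
        p_binomial=float("nan"),
        p_empirical=p_emp,
        z=z,
        n_resamples=n_resamples,
        null_skewness=float(sps.skew(null)) if sd > 0 else float("nan"),
    )
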