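"""TAD segmentation from a contact matrix and the TAD-quartile analyses.

Topologically associating domains are called from the directionality index
(DI): per bin, the signed chi-square-style statistic comparing upstream and
downstream contact sums within a window.  Boundaries are placed where a
sustained-negative DI run is followed by a sustained-positive run; domains
are the intervals between boundaries.  Downstream analyses divide TADs with
breakpoints into breakpoint-frequency quartiles and quantify the fraction of
each TAD spanned by transcriptional features, optionally normalized by the
TAD's transcribed area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import GenomicInterval, coverage_fraction, intersect_bp


def directionality_index(matrix: np.ndarray, window_bins: int = 40) -> pd.DataFrame:
    """Per-bin DI profile of a symmetric contact matrix.

    For bin i: A = sum of contacts to the ``window_bins`` bins upstream,
    B = the same downstream, E = (A+B)/2, and
    di = sign(B-A) * ((A-E)^2/E + (B-E)^2/E); 0 when A+B = 0.  Edge bins
    use truncated windows.
    """
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("contact matrix must be symmetric")
    n = m.shape[0]
    a = np.empty(n)
    b = np.empty(n)
    for i in range(n):
        a[i] = m[i, max(0, i - window_bins):i].sum()
        b[i] = m[i, i + 1:min(n, i + 1 + window_bins)].sum()
    e = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = (a - e) ** 2 / e + (b - e) ** 2 / e
    di = np.sign(b - a) * chi
    di[(a + b) == 0] = 0.0
    return pd.DataFrame({"bin": np.arange(n), "A": a, "B": b, "E": e, "di": di})


def call_tads(
    di_profile: pd.DataFrame,
    min_size_bins: int = 3,
    bin_width: int = 50_000,
    chrom: str = "chr1",
    chrom_length: int | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Domain boundaries at sustained negative-to-positive DI transitions.

    A run counts when it keeps one sign for >= ``min_size_bins`` bins with
    |di| above the profile's median absolute value; a boundary is placed at
    the first bin of the positive run that follows a qualifying negative
    run.  Returns (domains frame, boundary bin indices).
    """
    di = di_profile["di"].to_numpy()
    n = len(di)
    thresh = float(np.median(np.abs(di)))
    state = np.zeros(n, dtype=int)
    state[di > thresh] = 1
    state[di < -thresh] = -1
    # group nonzero-state bins into same-sign runs; zero bins are neutral
    # and do not break a run
    runs: list[tuple[int, int, int]] = []  # (sign, first_bin, n_bins_in_run)
    for i in np.flatnonzero(state):
        if runs and runs[-1][0] == state[i]:
            sign, start, count = runs[-1]
            runs[-1] = (sign, start, count + 1)
        else:
            runs.append((int(state[i]), int(i), 1))
    qualified = [(s, st, ln) for s, st, ln in runs if ln >= min_size_bins]
    boundaries: list[int] = []
    for prev, cur in zip(qualified[:-1], qualified[1:]):
        if prev[0] == -1 and cur[0] == 1:
            boundaries.append(cur[1])
    edges = [0] + boundaries + [n]
    length = chrom_length if chrom_length is not None else n * bin_width
    rows = [
        (chrom, e0 * bin_width, min(e1 * bin_width, length))
        for e0, e1 in zip(edges[:-1], edges[1:])
        if min(e1 * bin_width, length) > e0 * bin_width
    ]
    domains = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return domains, boundaries


def tad_breakpoint_quartiles(tads: pd.DataFrame, breakpoints: pd.DataFrame) -> pd.DataFrame:
    """Quartile TADs by breakpoint frequency per bp.

    Only TADs containing at least one breakpoint participate.  Quartile
    ranges are exclusive-lower / inclusive-upper at the 25/50/75 empirical
    percentiles of frequency.
    """
    out = tads.copy().reset_index(drop=True)
    counts = np.zeros(len(out), dtype=int)
    for i, tad in enumerate(out.itertuples(index=False)):
        sub = breakpoints[breakpoints["chrom"] == tad.chrom]
        counts[i] = int(((sub["pos"] >= tad.start) & (sub["pos"] < tad.end)).sum())
    out["n_breakpoints"] = counts
    out["bp_frequency"] = counts / (out["end"] - out["start"])
    out = out[out["n_breakpoints"] >= 1].reset_index(drop=True)
    if len(out) == 0:
        out["quartile"] = pd.Series(dtype=object)
        return out
    freq = out["bp_frequency"].to_numpy()
    q25, q50, q75 = np.percentile(freq, [25, 50, 75])
    labels = np.where(
        freq <= q25, "Q1", np.where(freq <= q50, "Q2", np.where(freq <= q75, "Q3", "Q4"))
    )
    out["quartile"] = labels
    return out


def tad_feature_span(
    tads: pd.DataFrame,
    features: pd.DataFrame,
    normalize_by_transcribed: bool = False,
    transcripts: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-TAD fraction spanned by features.

    Plain mode: feature bp within the TAD divided by TAD length.  Normalized
    mode: feature bp within the TAD divided by transcribed bp within the TAD
    (union of transcripts); NaN when the TAD has no transcribed bp.
    """
    if normalize_by_transcribed and transcripts is None:
        raise ValueError("normalized mode needs transcripts")
    spans = []
    for tad in tads.itertuples(index=False):
        region = GenomicInterval(tad.chrom, int(tad.start), int(tad.end))
        tad_frame = pd.DataFrame(
            [[region.chrom, region.start, region.end]], columns=["chrom", "start", "end"]
        )
        if not normalize_by_transcribed:
            spans.append(coverage_fraction(region, features))
        else:
            trans_bp = intersect_bp(tad_frame, transcripts)
            if trans_bp == 0:
                spans.append(np.nan)
            else:
                spans.append(intersect_bp(tad_frame, features) / trans_bp)
    return pd.Series(spans, index=tads.index, name="span")


def quartile_enrichment_test(tads: pd.DataFrame, span_col: str = "span") -> pd.DataFrame:
    """Hypergeometric enrichment of high-span TADs per breakpoint quartile.

    TADs with span above the all-TAD median are "high"; for each quartile
    the upper-tail hypergeometric p compares its high count against the
    whole TAD population.
    """
    spans = tads[span_col].to_numpy(dtype=float)
    med = np.nanmedian(spans)
    high = spans > med
    pop_size = len(tads)
    pop_success = int(high.sum())
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        mask = tads["quartile"].to_numpy() == q
        n_q = int(mask.sum())
        k_q = int((high & mask).sum())
        p = float(sps.hypergeom.sf(k_q - 1, pop_size, pop_success, n_q)) if n_q else np.nan
        rows.append((q, n_q, k_q, p))
    return pd.DataFrame(rows, columns=["quartile", "n_tads", "n_high_span", "p_hypergeom"])
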