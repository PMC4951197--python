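"""Desk-scale benchmark computations on synthetic data.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline stage, and returns the measured quantity: exact-oracle agreement
for the change-point solver and interval operations, parameter recovery for
planted stall segments and TAD boundaries, closed-form recovery for the
breakpoint-enrichment generator, and type-I calibration of the binomial
enrichment test.  The problem sizes are the generator defaults documented
in the methods note.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np
import pandas as pd

from .convt import detect_convt
from .intervals import as_regions
from .simulate import (
    SimulationSpec,
    simulate_breakpoints,
    simulate_contact_matrix,
    simulate_genome,
    simulate_tracks,
)
from .stalling import call_stalls, pelt_mean
from .stats import (
    binomial_enrichment,
    fisher_or,
    hypergeom_enrichment,
    sampling_null,
    wilcoxon_shift,
)
from .tads import call_tads, directionality_index


def _dp_changepoints(x: np.ndarray, penalty: float) -> tuple[list[int], float]:
    """Unpruned O(n^2) segment-neighborhood dynamic program (reference)."""
    n = len(x)
    cum = np.concatenate(([0.0], np.cumsum(x)))
    cum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        s = np.arange(t)
        costs = f[s] + (cum2[t] - cum2[s]) - (cum[t] - cum[s]) ** 2 / (t - s) + penalty
        best = int(np.argmin(costs))
        f[t] = costs[best]
        prev[t] = best
    cps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps), float(f[n])


def _segmentation_cost(x: np.ndarray, cps: list[int], penalty: float) -> float:
    bounds = [0] + list(cps) + [len(x)]
    total = len(cps) * penalty
    for s, t in zip(bounds[:-1], bounds[1:]):
        seg = x[s:t]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total


def pelt_dp_agreement(seed: int, n_series: int = 50) -> float:
    """Fraction of random series where PELT and the exact DP agree on both
    the breakpoints and the optimal cost."""
    rng = np.random.default_rng([seed, 101])
    agree = 0
    for trial in range(n_series):
        n = int(rng.integers(10, 201))
        x = rng.normal(size=n)
        if trial % 3 == 0:
            x[int(rng.integers(1, n - 1)):] += rng.uniform(1, 5)
        penalty = 2 * math.log(n)
        got = pelt_mean(x, penalty)
        expect, f_opt = _dp_changepoints(x, penalty)
        if got == expect and np.isclose(_segmentation_cost(x, got, penalty), f_opt):
            agree += 1
    return agree / n_series


def stall_recovery_jaccard(seed: int, n_genes: int = 100) -> float:
    """Mean per-gene Jaccard of called vs planted stall segments
    (10x mean shift, baseline mean 10, segments >= 10 bins)."""
    spec = SimulationSpec(
        seed=seed, n_genes=n_genes, n_chroms=2, chrom_length=2_000_000,
        stall_fraction=1.0, stall_shift=10.0, baseline_mu=10.0, antisense_fraction=0.0,
    )
    chrom_sizes, transcripts = simulate_genome(spec)
    plus, minus, truth, _ = simulate_tracks(spec, chrom_sizes, transcripts)
    calls = call_stalls(transcripts, plus, minus, quantile=0.9)
    jaccards = []
    for g in transcripts.itertuples(index=False):
        tset, cset = set(), set()
        for r in truth[truth["name"] == g.name].itertuples(index=False):
            tset.update(range(r.start // 50, r.end // 50))
        for r in calls[calls["gene_id"] == g.name].itertuples(index=False):
            cset.update(range(r.start // 50, r.end // 50))
        if tset or cset:
            jaccards.append(len(tset & cset) / len(tset | cset))
    return float(np.mean(jaccards))


def convt_oracle_agreement(seed: int, n_transcripts: int = 200) -> float:
    """1.0 iff convT calls on random stranded transcripts equal the per-bp
    both-strands-transcribed bitmap runs of >= 100 bp."""
    rng = np.random.default_rng([seed, 102])
    size = 100_000
    rows = []
    for i in range(n_transcripts):
        s = int(rng.integers(0, size - 5_000))
        rows.append(("chr1", s, s + int(rng.integers(50, 5_000)), f"t{i}", 1.0,
                     "+" if rng.random() < 0.5 else "-"))
    t = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "rpkm", "strand"])
    got = detect_convt(t, 100)
    plus = np.zeros(size + 5_000, dtype=bool)
    minus = np.zeros(size + 5_000, dtype=bool)
    for r in t.itertuples(index=False):
        (plus if r.strand == "+" else minus)[r.start:r.end] = True
    both = plus & minus
    padded = np.concatenate(([False], both, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1]).reshape(-1, 2)
    runs = [(int(s), int(e)) for s, e in edges if e - s >= 100]
    return 1.0 if list(zip(got["start"], got["end"])) == runs else 0.0


def stitch_properties(seed: int, n_breakpoints: int = 300) -> tuple[float, float]:
    """(count conservation, monotone coarsening) over distances
    {100, 1000, 10000}; each 1.0 when the property holds exactly."""
    from .breakpoints import stitch

    rng = np.random.default_rng([seed, 103])
    pos = np.sort(rng.integers(0, 2_000_000, size=n_breakpoints))
    df = pd.DataFrame({"chrom": "chr1", "pos": pos, "end": pos + 1,
                       "subtype": "sim", "rss_status": "NA"})
    conserved = True
    counts = []
    for d in (100, 1000, 10_000):
        res = stitch(df, distance=d)
        conserved &= int(res["n_breakpoints"].sum()) == n_breakpoints
        counts.append(len(res))
    monotone = counts == sorted(counts, reverse=True)
    return (1.0 if conserved else 0.0, 1.0 if monotone else 0.0)


def enrichment_recovery(seed: int) -> dict[str, float]:
    """Breakpoints drawn at odds 3 over a 10% feature set: observed overlap
    fraction (expected 0.25), its binomial SE, and the analytic/empirical
    p-value difference."""
    spec = SimulationSpec(seed=seed, feature_odds=3.0, n_breakpoints=300)
    chrom_sizes = {"chr1": 1_000_000}
    feature = as_regions([("chr1", i * 100_000, i * 100_000 + 10_000) for i in range(10)])
    bps = simulate_breakpoints(spec, chrom_sizes, feature)
    regions = pd.DataFrame(
        {"chrom": bps["chrom"], "start": bps["pos"], "end": bps["pos"] + 1}
    )
    universe = as_regions([("chr1", 0, 1_000_000)])
    from .intervals import intersects

    hits = intersects(regions, feature)
    k, n = int(hits.sum()), len(regions)
    analytic = binomial_enrichment(k, n, feature, universe, window=1000)
    empirical = sampling_null(regions, universe, feature, n_resamples=1000,
                              seed=seed, window=-1)
    expected = 3 * 0.1 / (3 * 0.1 + 0.9)
    se = math.sqrt(expected * (1 - expected) / n)
    return {
        "observed_fraction": k / n,
        "expected_fraction": expected,
        "se": se,
        "p_binomial": analytic.p_binomial,
        "p_empirical": empirical.p_empirical,
        "mc_se": math.sqrt(
            max(empirical.p_empirical * (1 - empirical.p_empirical), 1e-6)
            / empirical.n_resamples
        ),
        "z": empirical.z,
    }


def binomial_type1_rate(seed: int, n_sims: int = 1000, n_breakpoints: int = 200,
                        alpha: float = 0.05) -> float:
    """Rejection rate of the binomial enrichment test on uniform-null
    breakpoints over a 15% feature set."""
    rng = np.random.default_rng([seed, 104])
    genome = 1_000_000
    feature = as_regions([("chr1", i * 100_000, i * 100_000 + 15_000) for i in range(10)])
    universe = as_regions([("chr1", 0, genome)])
    f_start = feature["start"].to_numpy()
    f_end = feature["end"].to_numpy()
    rejections = 0
    for _ in range(n_sims):
        pos = rng.integers(0, genome, size=n_breakpoints)
        j = np.searchsorted(f_start, pos, side="right") - 1
        k = int(((j >= 0) & (pos < f_end[np.maximum(j, 0)])).sum())
        res = binomial_enrichment(k, n_breakpoints, feature, universe, window=1000)
        if res.p_binomial <= alpha:
            rejections += 1
    return rejections / n_sims


def tad_boundary_recall(seed: int, n_tads: int, tolerance_bins: int = 2) -> float:
    """Fraction of planted TAD boundaries recovered within ``tolerance_bins``
    by the directionality-index caller."""
    spec = SimulationSpec(seed=seed, n_tads=n_tads, tad_contact_enrichment=3.0)
    mat, truth, _ = simulate_contact_matrix(spec)
    di = directionality_index(mat, window_bins=20)
    _, called = call_tads(di, min_size_bins=3)
    if not truth:
        return 1.0
    found = sum(any(abs(b - t) <= tolerance_bins for b in called) for t in truth)
    return found / len(truth)


def exact_test_oracle_agreement(seed: int) -> float:
    """1.0 iff the binomial, hypergeometric, Fisher and Wilcoxon engines all
    match brute-force enumeration on small instances."""
    ok = True
    # binomial: k=3, n=10, p0=0.1
    uni = as_regions([("chr1", 0, 10_000)])
    feat = as_regions([("chr1", 0, 1_000)])
    p = binomial_enrichment(3, 10, feat, uni).p_binomial
    expect = sum(comb(10, i) * 0.1**i * 0.9 ** (10 - i) for i in range(3, 11))
    ok &= np.isclose(p, expect, rtol=1e-9)
    # hypergeometric
    got = hypergeom_enrichment(5, 8, 12, 30)
    expect = sum(comb(12, i) * comb(18, 8 - i) / comb(30, 8) for i in range(5, 9))
    ok &= np.isclose(got, expect, rtol=1e-9)
    # Fisher: conditional enumeration for (20, 5, 5, 20)
    a, b, c, d = 20, 5, 5, 20
    _, p_f, _ = fisher_or(a, b, c, d)
    r1, r2, c1 = a + b, c + d, a + c

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(r1 + r2, c1)

    p_obs = prob(a)
    expect = sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
                 if prob(x) <= p_obs * (1 + 1e-9))
    ok &= np.isclose(p_f, expect, rtol=1e-9)
    # Wilcoxon: full 924-permutation enumeration at n=m=6
    rng = np.random.default_rng([seed, 105])
    x = rng.normal(1.0, 1.0, size=6)
    y = rng.normal(0.0, 1.0, size=6)
    res = wilcoxon_shift(x, y)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs_w = ranks[:6].sum()
    mean_w = 6 * 13 / 2
    count = total = 0
    for idx in itertools.combinations(range(12), 6):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= abs(obs_w - mean_w) - 1e-9:
            count += 1
    ok &= np.isclose(res.p, count / total, rtol=1e-9)
    return 1.0 if ok else 0.0
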