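"""PELT change-point detection against the exact O(n^2) dynamic program."""

import math

import numpy as np
import pandas as pd
import pytest

from grosv.stalling import (
    annotation_match_filter,
    call_stall_segments,
    call_stalls,
    merge_stalls,
    pelt_mean,
    scale_gene_signal,
)
from grosv.track import StrandedBinnedTrack


def dp_oracle(x, penalty):
    """Exact O(n^2) segment-neighborhood dynamic program (no pruning)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    cum = np.concatenate(([0.0], np.cumsum(x)))
    cum2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def cost(s, t):
        return (cum2[t] - cum2[s]) - (cum[t] - cum[s]) ** 2 / (t - s)

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(1, n + 1):
        for s in range(t):
            c = f[s] + cost(s, t) + penalty
            if c < f[t]:
                f[t] = c
                prev[t] = s
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps), f[n]


def pelt_cost(x, cps, penalty):
    x = np.asarray(x, dtype=float)
    bounds = [0] + list(cps) + [len(x)]
    total = len(cps) * penalty
    for s, t in zip(bounds[:-1], bounds[1:]):
        seg = x[s:t]
        total += ((seg - seg.mean()) ** 2).sum()
    return total


def test_forced_single_changepoint():
    x = np.array([0.0] * 20 + [10.0] * 20)
    assert pelt_mean(x, penalty=2 * math.log(40)) == [20]


def test_infinite_penalty_gives_no_changepoints():
    rng = np.random.default_rng(0)
    assert pelt_mean(rng.normal(size=100), penalty=np.inf) == []


def test_constant_series_gives_no_changepoints():
    assert pelt_mean(np.full(50, 3.2), penalty=0.0) == []


def test_pelt_matches_exact_dp_on_random_series():
    rng = np.random.default_rng(123)
    for trial in range(50):
        n = int(rng.integers(10, 201))
        x = rng.normal(size=n)
        if trial % 3 == 0:  # plant a shift in a third of the cases
            a = int(rng.integers(1, n - 1))
            x[a:] += rng.uniform(1, 5)
        penalty = 2 * math.log(n)
        got = pelt_mean(x, penalty)
        expect, f_opt = dp_oracle(x, penalty)
        assert got == expect, f"trial {trial}"
        # dp f[n] = total SSE + n_changepoints * penalty
        assert pelt_cost(x, got, penalty) == pytest.approx(f_opt)


def test_adding_changepoint_never_increases_unpenalized_cost():
    rng = np.random.default_rng(8)
    x = rng.normal(size=80)
    base = pelt_cost(x, [], 0.0)
    with_cp = pelt_cost(x, [40], 0.0)
    assert with_cp <= base


def test_scaling_invariance_of_changepoints():
    rng = np.random.default_rng(5)
    raw = np.abs(rng.normal(10, 3, size=120))
    raw[40:60] *= 8
    for c in (0.1, 1.0, 37.5):
        z = scale_gene_signal(c * raw)
        np.testing.assert_allclose(z, scale_gene_signal(raw), atol=1e-9)
    z = scale_gene_signal(raw)
    assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9
    assert np.all(scale_gene_signal(np.full(10, 4.0)) == 0)


class Gene:
    def __init__(self, chrom, start, end, name, strand="+"):
        self.chrom, self.start, self.end, self.name, self.strand = chrom, start, end, name, strand


def make_track(values, sizes={"chr1": 100_000}):
    t = StrandedBinnedTrack(sizes, 50, "+")
    t.values["chr1"][:len(values)] = values
    return t


def test_flat_gene_has_no_stalls():
    t = make_track(np.full(100, 5.0))
    calls = call_stall_segments(Gene("chr1", 0, 5000, "g1"), t)
    assert len(calls) == 0


def test_planted_shift_segment_recovered_within_one_bin():
    rng = np.random.default_rng(33)
    vals = rng.poisson(10, size=200).astype(float)
    vals[80:100] *= 10  # planted stall: bins 80..100
    t = make_track(vals)
    calls = call_stall_segments(Gene("chr1", 0, 10_000, "g1"), t, quantile=0.9)
    assert len(calls) == 1
    assert abs(calls["start"].iloc[0] - 80 * 50) <= 50
    assert abs(calls["end"].iloc[0] - 100 * 50) <= 50


def test_relaxed_quantile_calls_superset():
    rng = np.random.default_rng(14)
    vals = rng.poisson(10, size=150).astype(float)
    vals[50:70] *= 6
    vals[100:110] *= 3
    t = make_track(vals)
    g = Gene("chr1", 0, 7500, "g1")
    strict = call_stall_segments(g, t, quantile=0.90)
    relaxed = call_stall_segments(g, t, quantile=0.80)
    strict_bins = set()
    for r in strict.itertuples(index=False):
        strict_bins.update(range(r.start, r.end))
    relaxed_bins = set()
    for r in relaxed.itertuples(index=False):
        relaxed_bins.update(range(r.start, r.end))
    assert strict_bins <= relaxed_bins


def test_short_genes_skipped(caplog):
    t = make_track(np.ones(10))
    tr = pd.DataFrame(
        [("chr1", 0, 100, "tiny", 1.0, "+")],
        columns=["chrom", "start", "end", "name", "rpkm", "strand"],
    )
    assert len(call_stalls(tr, t)) == 0


def test_merge_stalls_uses_100bp_gap():
    segs = pd.DataFrame(
        [("chr1", 0, 100), ("chr1", 150, 300), ("chr1", 500, 600)],
        columns=["chrom", "start", "end"],
    )
    merged = merge_stalls(segs, gap=100)
    assert list(zip(merged["start"], merged["end"])) == [(0, 300), (500, 600)]


def trx(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "rpkm", "strand"])


def test_annotation_match_filter_examples():
    det = trx([("chr1", 1000, 2000, "d1", 1.0, "+")])
    ann = trx([("chr1", 1000, 2000, "a1", 1.0, "+")])
    assert len(annotation_match_filter(det, ann)) == 1  # identical kept
    # 100-kb detected vs 1-kb annotation inside: 1% coverage < 5% -> dropped
    det2 = trx([("chr1", 0, 100_000, "d2", 1.0, "+")])
    ann2 = trx([("chr1", 0, 1_000, "a2", 1.0, "+")])
    assert len(annotation_match_filter(det2, ann2)) == 0
    # opposite strand never matches
    ann3 = trx([("chr1", 1000, 2000, "a3", 1.0, "-")])
    assert len(annotation_match_filter(det, ann3)) == 0
    # TSS difference > 10 kb rejected even with good coverage
    det4 = trx([("chr1", 0, 100_000, "d4", 1.0, "+")])
    ann4 = trx([("chr1", 60_000, 100_000, "a4", 1.0, "+")])
    assert len(annotation_match_filter(det4, ann4)) == 0


def test_annotation_match_filter_equals_three_clause_oracle():
    rng = np.random.default_rng(77)
    det_rows, ann_rows = [], []
    for i in range(60):
        s = int(rng.integers(0, 80_000))
        det_rows.append(("chr1", s, s + int(rng.integers(1_000, 30_000)), f"d{i}", 1.0,
                         "+" if rng.random() < 0.5 else "-"))
    for i in range(60):
        s = int(rng.integers(0, 80_000))
        ann_rows.append(("chr1", s, s + int(rng.integers(1_000, 30_000)), f"a{i}", 1.0,
                         "+" if rng.random() < 0.5 else "-"))
    det, ann = trx(det_rows), trx(ann_rows)
    kept = set(annotation_match_filter(det, ann)["name"])
    for d in det.itertuples(index=False):
        expect = False
        d_tss = d.start if d.strand == "+" else d.end
        for a in ann.itertuples(index=False):
            if a.strand != d.strand:
                continue
            ov = min(d.end, a.end) - max(d.start, a.start)
            a_tss = a.start if a.strand == "+" else a.end
            if (
                ov > 0
                and ov >= 0.05 * (d.end - d.start)
                and ov >= 0.50 * (a.end - a.start)
                and abs(d_tss - a_tss) <= 10_000
            ):
                expect = True
                break
        assert (d.name in kept) == expect, d.name


def test_parameter_recovery_on_simulated_genes():
    """Planted 10x mean-shift segments are recovered at Jaccard >= 0.8."""
    from grosv.simulate import SimulationSpec, simulate_genome, simulate_tracks

    spec = SimulationSpec(
        seed=7, n_genes=100, n_chroms=2, chrom_length=2_000_000,
        stall_fraction=1.0, stall_shift=10.0, baseline_mu=10.0, antisense_fraction=0.0,
    )
    cs, tr = simulate_genome(spec)
    plus, minus, truth, _ = simulate_tracks(spec, cs, tr)
    calls = call_stalls(tr, plus, minus, quantile=0.9)
    jaccards = []
    for g in tr.itertuples(index=False):
        tset, cset = set(), set()
        for r in truth[truth["name"] == g.name].itertuples(index=False):
            tset.update(range(r.start // 50, r.end // 50))
        for r in calls[calls["gene_id"] == g.name].itertuples(index=False):
            cset.update(range(r.start // 50, r.end // 50))
        if tset or cset:
            jaccards.append(len(tset & cset) / len(tset | cset))
    assert np.mean(jaccards) >= 0.8
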