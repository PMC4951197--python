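"""RSS motif scanning, stitching and overlap analyses against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from grosv.breakpoints import (
    PWM,
    breakpoint_feature_overlap,
    classify_rss,
    cooccurrence,
    expression_binned_overlap,
    recurrence_bins,
    scan_window,
    stitch,
)
from grosv.simulate import rss_heptamer_pwm


def bps(positions, chrom="chr1", rss=None):
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "end": [p + 1 for p in positions],
            "subtype": "t",
            "rss_status": rss if rss is not None else ["NA"] * len(positions),
        }
    )
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


class TestPWM:
    def test_row_sum_validated(self):
        with pytest.raises(ValueError):
            PWM(probs=np.array([[0.5, 0.5, 0.1, 0.0]]))

    def test_consensus_scores_minimal_pvalue(self):
        pwm = rss_heptamer_pwm()
        p_cons = scan_window(pwm.consensus, pwm)
        # consensus maximizes the score, so its p equals the probability of
        # drawing a score >= max, the smallest achievable tail
        assert p_cons <= 0.003

    def test_reverse_complement_strand_symmetry(self):
        pwm = rss_heptamer_pwm()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(pwm.consensus))
        assert scan_window(rc, pwm) == scan_window(pwm.consensus, pwm)

    def test_window_with_n_is_nan(self):
        assert np.isnan(scan_window("CACNGTGAAAAAAAAAAAAAA", rss_heptamer_pwm()))

    def test_exact_pvalue_matches_enumeration_for_toy_pwm(self):
        """DP score-distribution p-values equal brute-force enumeration over
        all 4^4 sequences for a 4-position PWM."""
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(4), size=4)
        pwm = PWM(probs=raw)
        ints, pvalue = pwm.pvalue_lookup()
        bg = pwm.background
        # enumerate every 4-mer, accumulate exact tail probabilities
        scores, probs = [], []
        for kmer in itertools.product(range(4), repeat=4):
            s = int(sum(ints[i, b] for i, b in enumerate(kmer)))
            pr = float(np.prod([bg[b] for b in kmer]))
            scores.append(s)
            probs.append(pr)
        scores = np.array(scores)
        probs = np.array(probs)
        for s in np.unique(scores):
            expect = probs[scores >= s].sum()
            assert pvalue(int(s)) == pytest.approx(expect, rel=1e-9)

    def test_background_false_positive_rate_bounded(self):
        """Random background sequences rarely reach p <= 0.003 per position
        family (<= alpha per scan position before correction)."""
        pwm = rss_heptamer_pwm()
        rng = np.random.default_rng(5)
        n = 400
        hits = 0
        for _ in range(n):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=21))
            if scan_window(seq, pwm) <= 0.003:
                hits += 1
        n_scans = 2 * (21 - pwm.width + 1)
        assert hits / n <= 0.003 * n_scans + 3 * np.sqrt(0.003 * n_scans / n)


class TestClassify:
    def test_planted_consensus_is_r_and_random_is_nr(self):
        pwm = rss_heptamer_pwm()
        genome = {"chr1": "A" * 100 + "CACAGTG" + "A" * 100}
        res = classify_rss(bps([103, 50]), genome, pwm)
        by_pos = dict(zip(res["pos"], res["rss_status"]))
        assert by_pos[103] == "R"  # window covers the planted heptamer
        assert by_pos[50] == "NR"

    def test_missing_chromosome_is_na_with_warning(self):
        pwm = rss_heptamer_pwm()
        with pytest.warns(UserWarning, match="missing"):
            res = classify_rss(bps([10], chrom="chrX"), {"chr1": "A" * 100}, pwm)
        assert res["rss_status"].iloc[0] == "NA"


class TestStitch:
    def test_chain_rule_examples(self):
        res = stitch(bps([0, 900, 2500]), distance=1000)
        assert res["n_breakpoints"].tolist() == [2, 1]
        assert res[["start", "end"]].values.tolist() == [[0, 901], [2500, 2501]]
        res3 = stitch(bps([0, 1000, 2000]), distance=1000)
        assert res3["n_breakpoints"].tolist() == [3]

    def test_count_conserved_and_matches_union_find(self):
        rng = np.random.default_rng(17)
        positions = sorted(int(p) for p in rng.integers(0, 200_000, size=300))
        df = bps(positions)
        for d in (100, 1000, 10_000):
            res = stitch(df, distance=d)
            assert res["n_breakpoints"].sum() == len(df)
            # union-find oracle on the <= d graph
            parent = list(range(len(positions)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(positions)):
                for j in range(i + 1, len(positions)):
                    if abs(positions[j] - positions[i]) <= d:
                        parent[find(i)] = find(j)
            n_components = len({find(i) for i in range(len(positions))})
            assert len(res) == n_components

    def test_monotone_coarsening(self):
        rng = np.random.default_rng(3)
        df = bps(sorted(int(p) for p in rng.integers(0, 500_000, size=200)))
        counts = [len(stitch(df, distance=d)) for d in (100, 1000, 10_000)]
        assert counts == sorted(counts, reverse=True)

    def test_rss_class_prioritizes_r(self):
        res = stitch(bps([0, 100, 5000], rss=["NR", "R", "NA"]), distance=1000)
        assert res["rss_class"].tolist() == ["R", "NA"]


def test_recurrence_bins_labels():
    regions = pd.DataFrame({"n_breakpoints": [1, 2, 3, 5]})
    out = recurrence_bins(regions)
    assert out["recurrence_bin"].tolist() == ["1", ">1", ">2", ">4"]
    with pytest.raises(ValueError):
        recurrence_bins(regions, cutoffs=(4, 1))


def regions_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestOverlap:
    def test_all_inside_and_all_disjoint(self):
        regions = regions_frame([("chr1", 100, 200), ("chr1", 5000, 5100)])
        feats = regions_frame([("chr1", 0, 10_000)])
        assert breakpoint_feature_overlap(regions, feats, 1000)[0] == 1.0
        far = regions_frame([("chr1", 50_000, 50_100)])
        assert breakpoint_feature_overlap(regions, far, 1000)[0] == 0.0
        with pytest.raises(ValueError):
            breakpoint_feature_overlap(regions_frame([]), feats, 1000)

    def test_intragenic_restriction(self):
        regions = regions_frame([("chr1", 100, 200), ("chr1", 90_000, 90_100)])
        genes = regions_frame([("chr1", 0, 1_000)])
        feats = regions_frame([("chr1", 150, 160)])
        frac, flags = breakpoint_feature_overlap(regions, feats, 1000, genes=genes)
        assert frac == 1.0 and len(flags) == 1  # only the intragenic region counted

    def test_cooccurrence_table_matches_per_region_oracle(self):
        rng = np.random.default_rng(9)
        regions = regions_frame(
            [("chr1", int(p), int(p) + 100) for p in rng.integers(0, 100_000, 80)]
        )
        convt = regions_frame([("chr1", i * 10_000, i * 10_000 + 2_000) for i in range(10)])
        stalls = regions_frame([("chr1", i * 7_000, i * 7_000 + 1_000) for i in range(12)])
        table = cooccurrence(regions, convt, stalls, window=500)
        both = either = 0
        from grosv.intervals import windowed_overlap

        fc = windowed_overlap(regions, convt, 500)
        fs = windowed_overlap(regions, stalls, 500)
        for c, s in zip(fc, fs):
            both += c and s
            either += c or s
        assert table["both"] == both and table["either"] == either
        assert sum(table[k] for k in ("both", "convt_only", "stall_only", "neither")) == len(regions)
        # identical feature sets: both == either
        t2 = cooccurrence(regions, convt, convt, window=500)
        assert t2["both"] == t2["either"]

    def test_expression_quartile_membership_matches_sort_oracle(self):
        rng = np.random.default_rng(30)
        genes = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(16) * 5_000,
                "end": np.arange(16) * 5_000 + 4_000,
                "name": [f"g{i}" for i in range(16)],
                "rpkm": rng.permutation(np.arange(16, dtype=float)),
                "strand": "+",
            }
        )
        # features only inside the 4 highest-expressed genes
        top4 = genes.nlargest(4, "rpkm")
        feats = top4[["chrom", "start", "end"]].reset_index(drop=True)
        regions = genes[["chrom", "start", "end"]].copy()
        regions["start"] += 100
        regions["end"] = regions["start"] + 50
        res = expression_binned_overlap(regions, genes, feats, window=0)
        assert res.loc[res["quartile"] == "Q4", "fraction"].iloc[0] == 1.0
        assert res.loc[res["quartile"] == "Q1", "fraction"].iloc[0] == 0.0
        # quartile sizes from the sort oracle: 4 genes -> 4 regions each
        assert res["n_regions"].tolist() == [4, 4, 4, 4]
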