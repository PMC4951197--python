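"""Synthetic genomes, tracks, breakpoints and contact matrices.

The generator emulates the statistical structure the downstream analyses
assume: stranded per-gene count signal with negative-binomial (overdispersed)
noise, injected mean-shift stall segments, antisense transcripts creating
convergent-transcription overlaps, breakpoints drawn with a controlled odds
of landing inside a feature set, and TAD-blocked Poisson contact matrices
with 1/(1+d) distance decay.  All randomness flows from integer-seeded
streams (one per component), so outputs are byte-identical across runs and
platforms; every truth table is a valid input to the corresponding analysis
module without schema adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breakpoints import PWM
from .intervals import REGION_COLS, merge_intervals, subtract_regions, total_bp
from .track import StrandedBinnedTrack

# canonical RSS heptamer consensus (synthetic stand-in motif)
RSS_CONSENSUS = "CACAGTG"


def rss_heptamer_pwm(strength: float = 0.97) -> PWM:
    """Synthetic PWM for the RSS heptamer CACAGTG.

    A stand-in built from the consensus with ``strength`` probability on the
    consensus base at each position, uniform elsewhere.
    """
    probs = np.full((len(RSS_CONSENSUS), 4), (1 - strength) / 3)
    for i, b in enumerate(RSS_CONSENSUS):
        probs[i, "ACGT".index(b)] = strength
    return PWM(probs=probs, name="RSS_heptamer_synthetic")


@dataclass
class SimulationSpec:
    """Generator parameters; defaults define the standard desk-scale study
    conditions used throughout the test-suite and the acceptance run."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    baseline_mu: float = 10.0
    nb_dispersion: float = 10.0
    stall_fraction: float = 0.3
    stall_shift: float = 10.0
    stall_length_range: tuple[int, int] = (500, 2_000)
    antisense_fraction: float = 0.3
    n_breakpoints: int = 300
    feature_odds: float = 3.0
    n_tads: int = 5
    tad_contact_enrichment: float = 4.0
    hic_mu: float = 100.0
    hic_chrom_length: int = 10_000_000  # TADs ~1-2 Mb, so a longer axis than the signal genome
    bin_width: int = 50
    hic_bin: int = 50_000
    convt_min_overlap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stall_fraction", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.feature_odds <= 0:
            raise ValueError("feature_odds must be positive")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_tads", "bin_width", "hic_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, component: int) -> np.random.Generator:
        """Independent integer-seeded stream per generator component."""
        return np.random.default_rng([self.seed, component])


def simulate_genome(spec: SimulationSpec) -> tuple[dict[str, int], pd.DataFrame]:
    """Place non-overlapping same-strand genes; a fraction receive a shorter
    overlapping antisense transcript (the convT source).

    Gene coordinates are snapped to the signal bin grid so that injected
    signal structure aligns with track bins.  Returns (chrom_sizes,
    transcripts) where transcripts carry chrom/start/end/name/rpkm/strand
    and a ``kind`` column (gene / antisense).
    """
    rng = spec.rng(1)
    bw = spec.bin_width
    chrom_sizes = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    rows = []
    gene_no = 0
    for ci, (chrom, n_here) in enumerate(zip(chrom_sizes, per_chrom)):
        # primary genes never overlap each other on either strand, so all
        # convergent transcription traces back to the antisense partners
        placed: list[tuple[int, int]] = []
        for _ in range(n_here):
            length = int(rng.integers(*spec.gene_length_range) // bw * bw) or bw
            strand = "+" if rng.random() < 0.5 else "-"
            for attempt in range(200):
                start = int(rng.integers(0, (spec.chrom_length - length) // bw)) * bw
                end = start + length
                if all(e <= start or s >= end for s, e in placed):
                    break
            else:
                raise RuntimeError(
                    "could not place genes without overlap; reduce n_genes"
                )
            placed.append((start, end))
            gene_no += 1
            rpkm = float(5.0 * rng.lognormal(0.0, 0.5))
            rows.append((chrom, start, end, f"gene_{gene_no:04d}", rpkm, strand, "gene"))
    genes = pd.DataFrame(
        rows, columns=REGION_COLS + ["name", "rpkm", "strand", "kind"]
    )
    # antisense partners: shorter opposite-strand transcripts fully inside
    # the host gene, overlap >= convt_min_overlap
    n_as = int(round(spec.antisense_fraction * len(genes)))
    hosts = rng.choice(len(genes), size=n_as, replace=False) if n_as else np.array([], int)
    as_rows = []
    for k, gi in enumerate(sorted(hosts)):
        g = genes.iloc[gi]
        glen = g.end - g.start
        max_len = min(glen, 5_000) // bw * bw
        min_len = -(-spec.convt_min_overlap // bw) * bw
        length = int(rng.integers(min_len // bw, max_len // bw + 1)) * bw if max_len > min_len else min_len
        start = g.start + int(rng.integers(0, (glen - length) // bw + 1)) * bw
        strand = "-" if g.strand == "+" else "+"
        rpkm = float(2.0 * rng.lognormal(0.0, 0.5))
        as_rows.append(
            (g.chrom, start, start + length, f"as_{k + 1:04d}", rpkm, strand, "antisense")
        )
    if as_rows:
        transcripts = pd.concat(
            [genes, pd.DataFrame(as_rows, columns=genes.columns)], ignore_index=True
        )
    else:
        transcripts = genes
    transcripts = transcripts.sort_values(REGION_COLS, kind="mergesort").reset_index(drop=True)
    return chrom_sizes, transcripts


def simulate_tracks(
    spec: SimulationSpec,
    chrom_sizes: dict[str, int],
    transcripts: pd.DataFrame,
) -> tuple[StrandedBinnedTrack, StrandedBinnedTrack, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial stranded bin signal with injected stall segments.

    Per transcript, sense-strand bins draw from NB with mean
    ``baseline_mu * rpkm/5`` (rpkm 5 is the generator's median expression);
    inside each injected stall segment the mean is multiplied by
    ``stall_shift``.  Bins outside any transcript draw from NB with mean
    ``baseline_mu / 20``.  Returns (plus, minus, truth_stalls, truth_convt);
    truth convT is the opposite-strand overlap geometry of the transcripts.
    """
    from .convt import detect_convt

    rng = spec.rng(2)
    bw = spec.bin_width
    tracks = {
        "+": StrandedBinnedTrack(chrom_sizes, bin_width=bw, strand="+"),
        "-": StrandedBinnedTrack(chrom_sizes, bin_width=bw, strand="-"),
    }
    covered = {s: {c: np.zeros(len(v), dtype=bool) for c, v in tracks[s].values.items()}
               for s in "+-"}
    genes = transcripts[transcripts["kind"] == "gene"] if "kind" in transcripts else transcripts
    n_stall = int(round(spec.stall_fraction * len(genes)))
    stall_hosts = set(
        rng.choice(genes.index.to_numpy(), size=n_stall, replace=False).tolist()
    ) if n_stall else set()
    truth_rows = []
    for idx, tr in transcripts.iterrows():
        arr = tracks[tr.strand].values[tr.chrom]
        b0, b1 = tr.start // bw, tr.end // bw  # grid-aligned by construction
        nb = b1 - b0
        mu = np.full(nb, spec.baseline_mu * tr.rpkm / 5.0)
        if idx in stall_hosts and spec.stall_shift != 1.0:
            lo, hi = spec.stall_length_range
            seg_bins = max(1, int(rng.integers(lo, hi + 1)) // bw)
            seg_bins = min(seg_bins, nb)
            s = int(rng.integers(0, nb - seg_bins + 1))
            mu[s:s + seg_bins] *= spec.stall_shift
            truth_rows.append(
                (tr.chrom, (b0 + s) * bw, (b0 + s + seg_bins) * bw, tr["name"])
            )
        size = spec.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
        arr[b0:b1] += counts
        covered[tr.strand][tr.chrom][b0:b1] = True
    bg_mu = spec.baseline_mu / 20.0
    for strand in "+-":
        for chrom, arr in tracks[strand].values.items():
            free = ~covered[strand][chrom]
            n_free = int(free.sum())
            size = spec.nb_dispersion
            arr[free] = rng.negative_binomial(size, size / (size + bg_mu), size=n_free)
    truth_stalls = pd.DataFrame(truth_rows, columns=REGION_COLS + ["name"])
    truth_convt = detect_convt(transcripts, min_overlap=spec.convt_min_overlap)
    return tracks["+"], tracks["-"], truth_stalls, truth_convt


def simulate_breakpoints(
    spec: SimulationSpec,
    chrom_sizes: dict[str, int],
    features: pd.DataFrame,
    r_fraction: float = 0.5,
) -> pd.DataFrame:
    """Point breakpoints with controlled odds of landing inside features.

    With feature genome-fraction f and odds ratio w, each breakpoint falls
    inside the feature union with probability w*f / (w*f + (1-f)), uniformly
    within the chosen side.  A ``truth_inside`` flag records the draw and a
    ``truth_rss`` flag marks the r_fraction of breakpoints designated to
    carry a planted motif (see :func:`simulate_genome_sequence`).
    """
    rng = spec.rng(3)
    if spec.n_breakpoints == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "end", "subtype", "rss_status", "truth_inside", "truth_rss"]
        )
    genome_bp = sum(chrom_sizes.values())
    feats = merge_intervals(features)
    f_bp = total_bp(feats)
    if f_bp == 0 and spec.feature_odds != 1.0:
        raise ValueError("feature set empty with feature_odds != 1")
    f = f_bp / genome_bp
    w = spec.feature_odds
    p_inside = (w * f) / (w * f + (1 - f)) if f_bp else 0.0
    genome = pd.DataFrame(
        [(c, 0, length) for c, length in chrom_sizes.items()], columns=REGION_COLS
    )
    outside = subtract_regions(genome, feats)
    rows = []
    for i in range(spec.n_breakpoints):
        inside = rng.random() < p_inside
        pool = feats if inside else outside
        lens = (pool["end"] - pool["start"]).to_numpy()
        j = rng.choice(len(pool), p=lens / lens.sum())
        pos = int(pool["start"].iloc[j] + rng.integers(0, lens[j]))
        rows.append((pool["chrom"].iloc[j], pos, pos + 1, "sim", "NA",
                     bool(inside), bool(rng.random() < r_fraction)))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "end", "subtype", "rss_status", "truth_inside", "truth_rss"]
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_genome_sequence(
    spec: SimulationSpec,
    chrom_sizes: dict[str, int],
    breakpoints: pd.DataFrame | None = None,
    consensus: str = RSS_CONSENSUS,
) -> dict[str, str]:
    """Uniform-random genome sequence with the motif consensus planted at
    every breakpoint flagged ``truth_rss`` (centered on the position)."""
    rng = spec.rng(5)
    bases = np.array(list("ACGT"))
    seqs = {
        chrom: rng.integers(0, 4, size=length) for chrom, length in chrom_sizes.items()
    }
    if breakpoints is not None and len(breakpoints):
        codes = np.array([("ACGT").index(b) for b in consensus])
        half = len(consensus) // 2
        for bp in breakpoints.itertuples(index=False):
            if not getattr(bp, "truth_rss", False):
                continue
            s = bp.pos - half
            if s < 0 or s + len(consensus) > chrom_sizes[bp.chrom]:
                continue
            seqs[bp.chrom][s:s + len(consensus)] = codes
    return {chrom: "".join(bases[v]) for chrom, v in seqs.items()}


def simulate_contact_matrix(
    spec: SimulationSpec, chrom: str = "chr1", chrom_length: int | None = None
) -> tuple[np.ndarray, list[int], pd.DataFrame]:
    """TAD-blocked symmetric Poisson contact matrix with 1/(1+d) decay.

    ``n_tads`` equal blocks tile the chromosome; the expected count is
    ``hic_mu/(1+d)`` within a block and ``hic_mu/enrichment/(1+d)`` between
    blocks.  Returns (matrix, truth boundary bin indices, truth TAD frame).
    """
    rng = spec.rng(4)
    length = chrom_length if chrom_length is not None else spec.hic_chrom_length
    n_bins = -(-length // spec.hic_bin)
    if spec.n_tads > n_bins:
        raise ValueError("more TADs than matrix bins")
    edges = np.linspace(0, n_bins, spec.n_tads + 1).round().astype(int)
    block_of = np.zeros(n_bins, dtype=int)
    for b, (s, e) in enumerate(zip(edges[:-1], edges[1:])):
        block_of[s:e] = b
    i, j = np.triu_indices(n_bins)
    within = block_of[i] == block_of[j]
    d = j - i
    mu = np.where(within, spec.hic_mu, spec.hic_mu / spec.tad_contact_enrichment) / (1.0 + d)
    vals = rng.poisson(mu)
    mat = np.zeros((n_bins, n_bins))
    mat[i, j] = vals
    mat[j, i] = vals
    boundaries = [int(e) for e in edges[1:-1]]
    tads = pd.DataFrame(
        [
            (chrom, int(s) * spec.hic_bin, min(int(e) * spec.hic_bin, length))
            for s, e in zip(edges[:-1], edges[1:])
        ],
        columns=REGION_COLS,
    )
    return mat, boundaries, tads


def simulate_peaks(
    spec: SimulationSpec,
    chrom_sizes: dict[str, int],
    n_peaks: int = 200,
    width_range: tuple[int, int] = (200, 1_000),
    widen_inside: pd.DataFrame | None = None,
    widen_by: int = 500,
    score_range: tuple[float, float] = (5.0, 50.0),
) -> pd.DataFrame:
    """Score-carrying peak set with optional planted extra width inside a
    designated region set (for width-comparison analyses)."""
    rng = spec.rng(6)
    chroms = list(chrom_sizes)
    rows = []
    widen = merge_intervals(widen_inside) if widen_inside is not None else None
    for k in range(n_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        width = int(rng.integers(*width_range))
        start = int(rng.integers(0, chrom_sizes[chrom] - width - widen_by))
        end = start + width
        if widen is not None:
            sub = widen[widen["chrom"] == chrom]
            mid = (start + end) // 2
            if (((sub["start"] <= mid) & (sub["end"] > mid)).any()):
                end += widen_by
        score = float(rng.uniform(*score_range))
        rows.append((chrom, start, end, f"peak_{k + 1:04d}", score, "."))
    df = pd.DataFrame(rows, columns=REGION_COLS + ["name", "score", "strand"])
    return df.sort_values(REGION_COLS, kind="mergesort").reset_index(drop=True)
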