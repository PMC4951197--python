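import numpy as np
import pandas as pd
import pytest

from grosv.simulate import (
    SimulationSpec,
    simulate_genome,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def spec():
    return SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def dataset(spec):
    """One synthetic genome + tracks + truth tables shared across tests."""
    chrom_sizes, transcripts = simulate_genome(spec)
    plus, minus, truth_stalls, truth_convt = simulate_tracks(spec, chrom_sizes, transcripts)
    return {
        "chrom_sizes": chrom_sizes,
        "transcripts": transcripts,
        "plus": plus,
        "minus": minus,
        "truth_stalls": truth_stalls,
        "truth_convt": truth_convt,
    }


def random_regions(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, max_len=2_000):
    rows = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        rows.append((chrom, start, start + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)


def bitmap_union(df, size=200_000):
    """Per-chromosome boolean coverage bitmap — the brute-force oracle."""
    maps = {}
    for chrom, sub in df.groupby("chrom"):
        bm = np.zeros(size, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            bm[s:e] = True
        maps[chrom] = bm
    return maps
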