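"""Readers and writers for the on-disk formats the pipeline touches.

Everything is plain text: chrom.sizes, BED3/BED6, narrowPeak, bedGraph
(via :mod:`grosv.track`), breakpoint TSV, MEME minimal-format position
weight matrices, dense or sparse contact matrices, and FASTA (via pyfaidx).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import REGION_COLS, sort_regions

BED6_COLS = REGION_COLS + ["name", "score", "strand"]
NARROWPEAK_COLS = BED6_COLS + ["signalValue", "pValue", "qValue", "peak"]
BREAKPOINT_COLS = ["chrom", "pos", "end", "subtype", "rss_status"]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6 reader; returns as many of the six columns as present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = BED6_COLS[:ncol]
    return sort_regions(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    sort_regions(df)[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """ENCODE narrowPeak (10-column); ``score`` is column 5."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 10:
        raise ValueError(f"{path}: narrowPeak needs 10 columns, found {df.shape[1]}")
    df.columns = NARROWPEAK_COLS[:df.shape[1]]
    return sort_regions(df)


def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Transcript BED6: name = transcript id, score column = RPKM (optional).

    Returns columns chrom/start/end/name/rpkm/strand; rpkm is NaN when the
    score column is absent or '.'.
    """
    df = read_bed(path)
    if "strand" not in df.columns:
        raise ValueError(f"{path}: transcripts need 6 BED columns (strand required)")
    df = df.rename(columns={"score": "rpkm"})
    df["rpkm"] = pd.to_numeric(df["rpkm"], errors="coerce")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: transcripts must be stranded (+/-)")
    return df


def write_transcripts(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "rpkm" in out.columns:
        out["score"] = out["rpkm"].fillna(0.0).map(lambda v: f"{v:.4f}")
    else:
        out["score"] = "."
    write_bed(out, path)


def read_breakpoints(path: str | Path) -> pd.DataFrame:
    """Breakpoint TSV: chrom, pos, pos+1, subtype, rss_status (R/NR/NA).

    Missing trailing columns default to subtype='NA', rss_status='NA'.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str}, keep_default_na=False)
    ncol = min(df.shape[1], 5)
    df = df.iloc[:, :ncol]
    df.columns = BREAKPOINT_COLS[:ncol]
    for col, default in (("subtype", "NA"), ("rss_status", "NA")):
        if col not in df.columns:
            df[col] = default
    df["pos"] = df["pos"].astype(int)
    df["end"] = df["pos"] + 1
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_breakpoints(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["end"] = out["pos"] + 1
    out[BREAKPOINT_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_meme_pwm(path: str | Path):
    """Parse the first motif of a MEME minimal-format file into a PWM."""
    from .breakpoints import PWM

    background = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    rows: list[list[float]] = []
    name = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = {vals[j]: float(vals[j + 1]) for j in range(0, len(vals), 2)}
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            break
        i += 1
    if not rows:
        raise ValueError(f"{path}: no letter-probability matrix found")
    return PWM(
        probs=np.asarray(rows),
        background=np.array([background[b] for b in "ACGT"]),
        name=name or "motif",
    )


def read_contact_matrix(path: str | Path, n_bins: int | None = None) -> np.ndarray:
    """Read a binned contact matrix, dense TSV or 3-column sparse
    (bin_i TAB bin_j TAB count)."""
    first = open(path).readline().split("\t")
    if len(first) == 3 and n_bins is not None:
        tri = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "count"])
        mat = np.zeros((n_bins, n_bins))
        mat[tri["i"], tri["j"]] = tri["count"]
        mat[tri["j"], tri["i"]] = tri["count"]
        return mat
    mat = np.loadtxt(path, delimiter="\t")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: contact matrix must be square")
    return mat


def write_contact_matrix(mat: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, mat, delimiter="\t", fmt="%.6g")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def open_fasta(path: str | Path):
    """Indexed FASTA access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)
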