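"""Plain-text readers/writers for the interval and table formats used here.

BED and BEDPE are 0-based half-open; all tabular outputs are TSV with a
header row.  Matrix triplet I/O lives in :mod:`chromarch.matrix`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_bed", "write_bed", "read_bedpe", "write_bedpe",
    "read_table", "write_table", "write_bedgraph",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (3-6 columns) into chrom/start/end[/name/score/strand]."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_BED_COLS[:3])
    df.columns = _BED_COLS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read BEDPE-like tables: two anchors plus optional score columns."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start1", "end1",
                                     "chrom2", "start2", "end2"])
    base = ["chrom", "start1", "end1", "chrom2", "start2", "end2"]
    extra = [f"col{k}" for k in range(df.shape[1] - len(base))]
    df.columns = (base + extra)[: df.shape[1]]
    return df


def write_bedpe(df: pd.DataFrame, path: str | Path,
                extra_cols: list[str] | None = None) -> None:
    chrom2 = df["chrom2"] if "chrom2" in df.columns else df["chrom"]
    out = pd.DataFrame({
        "chrom1": df["chrom"], "start1": df["start1"], "end1": df["end1"],
        "chrom2": chrom2, "start2": df["start2"], "end2": df["end2"],
    })
    for c in extra_cols or []:
        out[c] = df[c]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_bedgraph(chrom: str, bin_size: int, values: np.ndarray,
                   path: str | Path) -> None:
    """Write a per-bin track as bedGraph-style TSV (NaN bins skipped)."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for b, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{b * bin_size}\t{(b + 1) * bin_size}\t{v:.6g}\n")
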