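"""Reading and writing of the pipeline's tabular formats.

All artifacts are plain text: counts as gene-by-sample TSV (or
MatrixMarket with companion row/column name files), sample sheets,
contrast and partition tables as TSV, growth curves and cytometry
events as CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_growth",
    "read_events",
    "write_table",
]


def read_counts(path: str) -> pd.DataFrame:
    """Read a count matrix from TSV (genes x samples) or MatrixMarket.

    For an ``.mtx`` file, gene and sample names are read from
    ``<stem>.rows.txt`` and ``<stem>.cols.txt`` next to it.
    """
    if path.endswith(".mtx"):
        stem = path[: -len(".mtx")]
        mat = spio.mmread(path)
        genes = _read_lines(stem + ".rows.txt")
        samples = _read_lines(stem + ".cols.txt")
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        counts = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative entries in count matrix")
    return counts.astype(np.int64, errors="ignore")


def write_counts(counts: pd.DataFrame, path: str, fmt: str = "tsv") -> None:
    """Write counts as TSV or as MTX plus row/col name files."""
    if fmt == "tsv":
        counts.to_csv(path, sep="\t")
    elif fmt == "mtx":
        stem = path[: -len(".mtx")] if path.endswith(".mtx") else path
        spio.mmwrite(stem + ".mtx", sparse.csr_matrix(counts.to_numpy()))
        _write_lines(stem + ".rows.txt", counts.index)
        _write_lines(stem + ".cols.txt", counts.columns)
    else:
        raise ValueError(f"unknown counts format {fmt!r}")


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read a sample sheet TSV (sample, strain, generation, line, replicate)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    required = {"strain", "generation", "line", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str) -> None:
    sheet.to_csv(path, sep="\t")


def read_growth(path: str) -> pd.DataFrame:
    """Read long-format growth curves (well, time_h, od)."""
    tab = pd.read_csv(path)
    missing = {"well", "time_h", "od"} - set(tab.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    return tab


def read_events(path: str) -> np.ndarray:
    """Read cytometry event intensities from CSV (column ``intensity``)."""
    tab = pd.read_csv(path)
    col = "intensity" if "intensity" in tab.columns else tab.columns[-1]
    return tab[col].to_numpy(dtype=float)


def write_table(table: pd.DataFrame, path: str, index: bool = True) -> None:
    """Write any result table as TSV, creating parent directories."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str, items) -> None:
    with open(path, "w") as fh:
        for item in items:
            fh.write(f"{item}\n")
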