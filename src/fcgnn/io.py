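"""Delimited-text formats: ROI time series, FC matrices, phenotype
tables, and edge-list exports.

All formats are plain TSV/CSV.  Time-series files are T rows x R
columns (optional header of region labels); FC files are R x R with the
subject id taken from the filename stem; phenotype tables carry
subject_id, label and optional site/subgroup columns; edge lists are
``i<TAB>j<TAB>weight`` with 0-based node indices.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    ConnectomeGraph,
    FCMatrix,
    ROITimeSeries,
    graph_from_edge_list,
    graph_to_edge_list,
)

__all__ = [
    "read_time_series",
    "read_fc_matrix",
    "write_fc_matrix",
    "read_fc_directory",
    "read_phenotype",
    "write_phenotype",
    "write_edge_list",
    "read_edge_list",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_time_series(path, subject_id: str | None = None) -> ROITimeSeries:
    """Read a T x R delimited time-series file; a non-numeric first row
    is treated as region labels."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    with open(path) as fh:
        rows = [line.strip().split(delim) for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty time-series file")
    labels = None
    try:
        float(rows[0][0])
    except ValueError:
        labels = [c.strip() for c in rows[0]]
        rows = rows[1:]
    try:
        values = np.array(rows, dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed time-series file: {exc}") from exc
    return ROITimeSeries(subject_id=subject_id or path.stem, values=values,
                         region_labels=labels)


def read_fc_matrix(path) -> FCMatrix:
    """Read an R x R delimited FC matrix; subject id = filename stem."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    try:
        z = np.loadtxt(path, delimiter=delim, dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FC matrix: {exc}") from exc
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError(f"{path}: FC matrix is not square "
                         f"(shape {z.shape})")
    return FCMatrix(subject_id=path.stem, z=z)


def write_fc_matrix(fc: FCMatrix, path) -> None:
    np.savetxt(path, fc.z, delimiter="\t", fmt="%.10g")


def read_fc_directory(directory) -> list[FCMatrix]:
    """Read every *.tsv / *.csv / *.txt FC file in a directory, sorted
    by subject id; all matrices must share the same R."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix in (".tsv", ".csv", ".txt"))
    if not files:
        raise ValueError(f"no FC matrix files found in {directory}")
    matrices = [read_fc_matrix(p) for p in files]
    sizes = {m.n_regions for m in matrices}
    if len(sizes) != 1:
        raise ValueError(
            f"FC matrices disagree on region count: {sorted(sizes)}")
    return matrices


def read_phenotype(path) -> pd.DataFrame:
    """Read the phenotype TSV (subject_id, label, optional site,
    subgroup); labels must be 0/1, subgroup text is normalised to
    upper case."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"subject_id": str})
    missing = {"subject_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if not df["label"].isin((0, 1)).all():
        raise ValueError("phenotype labels must be 0 or 1")
    if "subgroup" in df.columns:
        df["subgroup"] = df["subgroup"].astype(str).str.strip().str.upper()
    return df


def write_phenotype(path, subject_ids, labels, sites=None,
                    subgroups=None) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        header = ["subject_id", "label"]
        if sites is not None:
            header.append("site")
        if subgroups is not None:
            header.append("subgroup")
        w.writerow(header)
        for i, (sid, y) in enumerate(zip(subject_ids, labels)):
            row = [sid, int(y)]
            if sites is not None:
                row.append(sites[i])
            if subgroups is not None:
                row.append(subgroups[i])
            w.writerow(row)


def write_edge_list(g: ConnectomeGraph, path) -> None:
    """TSV export ``i<TAB>j<TAB>weight`` (i < j, lexicographic)."""
    with open(path, "w") as fh:
        for i, j, w in graph_to_edge_list(g):
            fh.write(f"{i}\t{j}\t{w:.10g}\n")


def read_edge_list(path, n_nodes: int,
                   node_features: np.ndarray | None = None,
                   subject_id: str = "") -> ConnectomeGraph:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                i, j, w = line.split("\t")
                rows.append((int(i), int(j), float(w)))
    return graph_from_edge_list(rows, n_nodes, node_features=node_features,
                                subject_id=subject_id)
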