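"""Delimited-text I/O: time-series matrices, connectivity matrices, trees,
metric tables and result bundles.  Everything round-trips at full float
precision; no binary formats."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .spectral import RoiTimeSeries
from .tree import SpanningTree

_FLOAT_FMT = "%.17g"


def read_timeseries(path: str | Path, fs: float, sep: str | None = None) -> RoiTimeSeries:
    """Read a samples x ROIs delimited matrix (header row of ROI labels)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate ROI labels in header")
    arr = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)):
        rows, cols = np.where(~np.isfinite(arr))
        raise ValueError(
            f"{path}: non-numeric/missing cell at row {int(rows[0]) + 2}, "
            f"column {labels[int(cols[0])]!r}"
        )
    return RoiTimeSeries(arr.T, fs, labels)


def write_timeseries(ts: RoiTimeSeries, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(ts.data.T, columns=ts.roi_labels)
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    """Square CSV with ROI labels as header row and index column."""
    df = pd.DataFrame(mat.values, index=mat.roi_labels, columns=mat.roi_labels)
    df.to_csv(path, float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(df.to_numpy(dtype=float), roi_labels=[str(c) for c in df.columns])


def write_tree(tree: SpanningTree, path: str | Path) -> None:
    """Edge-list TSV: node_i_label, node_j_label, pli_weight (N-1 rows)."""
    rows = [
        {"node_i": tree.node_labels[i], "node_j": tree.node_labels[j], "pli_weight": w}
        for i, j, w in tree.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tree(path: str | Path, node_labels: list[str]) -> SpanningTree:
    df = pd.read_csv(path, sep="\t")
    index = {lab: k for k, lab in enumerate(node_labels)}
    edges = [
        (min(index[r.node_i], index[r.node_j]), max(index[r.node_i], index[r.node_j]),
         float(r.pli_weight))
        for r in df.itertuples()
    ]
    return SpanningTree(len(node_labels), edges, list(node_labels))


def write_results(results: list, path: str | Path, alpha: float = 0.05) -> None:
    """Tidy TSV: one row per hypothesis with raw/adjusted p and a
    significance flag at ``alpha``."""
    rows = []
    for r in results:
        d = asdict(r)
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}
        d["significant"] = d.get("p_fdr", 1.0) < alpha
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return asdict(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
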