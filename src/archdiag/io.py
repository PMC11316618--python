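"""Reading and writing expression matrices and result tables.

Two dialects are supported for matrices:

* dense CSV: header row = gene labels, first column = cell labels;
* Matrix Market coordinate file plus two one-column label sidecars
  (``<stem>_cells.txt``, ``<stem>_genes.txt``).

A sidecar metadata CSV (``<stem>_meta.csv``) carries the per-cell
gradient and ground-truth order when present.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datasets import ExpressionDataset
from .errors import FormatError


def _sidecar_paths(path: str) -> dict:
    stem = os.path.splitext(path)[0]
    return {
        "cells": f"{stem}_cells.txt",
        "genes": f"{stem}_genes.txt",
        "meta": f"{stem}_meta.csv",
    }


def save_dataset(ds: ExpressionDataset, path: str, fmt: Optional[str] = None) -> None:
    """Write a dataset as CSV or MTX (+ label/metadata sidecars)."""
    fmt = fmt or _infer_format(path)
    side = _sidecar_paths(path)
    if fmt == "csv":
        df = pd.DataFrame(ds.matrix, index=ds.cell_labels, columns=ds.gene_labels)
        df.to_csv(path, float_format="%.17g")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(ds.matrix))
        with open(side["cells"], "w") as fh:
            fh.write("\n".join(ds.cell_labels) + "\n")
        with open(side["genes"], "w") as fh:
            fh.write("\n".join(ds.gene_labels) + "\n")
    else:
        raise FormatError(f"unknown format {fmt!r} (use 'csv' or 'mtx')")
    meta = {}
    if ds.gradient is not None:
        meta["gradient"] = ds.gradient
    if ds.true_order is not None:
        meta["true_order"] = ds.true_order
    if meta:
        pd.DataFrame({"cell": ds.cell_labels, **meta}).to_csv(side["meta"], index=False)


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".csv", ".tsv", ".txt"):
        return "csv"
    if ext == ".mtx":
        return "mtx"
    raise FormatError(f"cannot infer format from extension {ext!r}")


def load_matrix(path: str, fmt: Optional[str] = None) -> ExpressionDataset:
    """Load a dataset written by :func:`save_dataset` (or compatible).

    Values are validated to be finite and non-negative; offending
    entries are reported with their row/column labels.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    fmt = fmt or _infer_format(path)
    side = _sidecar_paths(path)
    if fmt == "csv":
        sep = "\t" if path.endswith(".tsv") else ","
        try:
            df = pd.read_csv(path, index_col=0, sep=sep)
            matrix = df.to_numpy(dtype=float)
        except (ValueError, pd.errors.ParserError) as err:
            raise FormatError(f"{path}: {err}") from err
        cells = [str(c) for c in df.index]
        genes = [str(g) for g in df.columns]
    elif fmt == "mtx":
        try:
            matrix = np.asarray(spio.mmread(path).todense(), dtype=float)
        except Exception as err:  # scipy raises bare ValueError on bad files
            raise FormatError(f"{path}: {err}") from err
        cells = _read_labels(side["cells"], matrix.shape[0], "cell")
        genes = _read_labels(side["genes"], matrix.shape[1], "gene")
    else:
        raise FormatError(f"unknown format {fmt!r} (use 'csv' or 'mtx')")

    bad = np.argwhere(~np.isfinite(matrix) | (matrix < 0))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: invalid value {matrix[i, j]!r} at row {cells[i]!r} "
            f"(line {i + 2}), column {genes[j]!r}")

    gradient = true_order = None
    if os.path.exists(side["meta"]):
        meta = pd.read_csv(side["meta"])
        if len(meta) != matrix.shape[0]:
            raise FormatError(
                f"{side['meta']}: {len(meta)} metadata rows for {matrix.shape[0]} cells")
        if "gradient" in meta:
            gradient = meta["gradient"].to_numpy(dtype=float)
        if "true_order" in meta:
            true_order = meta["true_order"].to_numpy(dtype=int)
    return ExpressionDataset(matrix=matrix, cell_labels=cells, gene_labels=genes,
                             gradient=gradient, true_order=true_order)


def _read_labels(path: str, expected: int, what: str) -> list[str]:
    if not os.path.exists(path):
        return [f"{what}_{i}" for i in range(expected)]
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if len(labels) != expected:
        raise FormatError(f"{path}: {len(labels)} labels for {expected} {what}s")
    return labels


def save_embedding(e, path: str, cell_labels=None) -> None:
    """Delimited embedding table (cell label, PC1..PCk) plus a sidecar
    with the component variances."""
    k = e.scores.shape[1]
    labels = cell_labels or [f"cell_{i}" for i in range(e.scores.shape[0])]
    df = pd.DataFrame(e.scores, index=labels,
                      columns=[f"PC{j + 1}" for j in range(k)])
    df.to_csv(path, float_format="%.17g")
    var_path = os.path.splitext(path)[0] + "_variances.txt"
    np.savetxt(var_path, e.component_variances)


def save_profile(profile, path: str) -> None:
    """Two-column table: ordered position, distance."""
    pd.DataFrame({
        "position": np.arange(profile.distances.size),
        "distance": profile.distances,
    }).to_csv(path, index=False, float_format="%.17g")


def save_curve(curve, path: str) -> None:
    """Vertex table with cumulative arc length."""
    d = curve.vertices.shape[1]
    df = pd.DataFrame(curve.vertices, columns=[f"dim{j + 1}" for j in range(d)])
    df["arc_length"] = curve.arc_lengths
    df.to_csv(path, index=False, float_format="%.17g")
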