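"""Reading and writing the on-disk formats.

Single-cell data travels as a Matrix Market triplet (genes x cells, the
CellRanger convention) with ``genes.tsv`` / ``cells.tsv`` name files and a
``cell_meta.tsv`` table; bulk cohorts as ``bulk_expr.tsv`` (samples x genes)
plus ``bulk_labels.tsv``; gene sets as plain lists or single-record GMT;
simulation ground truth as ``truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import BulkStudy, CellExpression, GeneSet
from .simulate import SimTruth

__all__ = [
    "write_cell_fixtures",
    "write_bulk_fixtures",
    "write_fixtures",
    "load_matrix",
    "load_dense",
    "load_bulk",
    "read_gene_set",
    "write_gmt",
    "read_truth",
]

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_cell_fixtures(
    x: CellExpression, out_dir: PathLike, truth: Optional[SimTruth] = None
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csc_matrix(x.counts.to_numpy().T)  # genes x cells
    scipy.io.mmwrite(out / "matrix.mtx", mat, field="integer")
    (out / "genes.tsv").write_text("\n".join(x.gene_ids) + "\n")
    (out / "cells.tsv").write_text("\n".join(x.cell_ids) + "\n")
    meta_cols = [
        c
        for c in x.cell_meta.columns
        if c not in ("detected_gene_count", "mito_fraction")
    ]
    x.cell_meta[meta_cols].to_csv(out / "cell_meta.tsv", sep="\t")
    files = {
        "mtx": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
        "meta": out / "cell_meta.tsv",
    }
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        files["truth"] = out / "truth.json"
    return files


def write_bulk_fixtures(
    b: BulkStudy, out_dir: PathLike, truth: Optional[SimTruth] = None
) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b.expr.to_csv(out / "bulk_expr.tsv", sep="\t")
    b.labels.to_frame().to_csv(out / "bulk_labels.tsv", sep="\t")
    files = {"expr": out / "bulk_expr.tsv", "labels": out / "bulk_labels.tsv"}
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        files["truth"] = out / "truth.json"
    return files


def write_fixtures(dataset, out_dir: PathLike, truth=None) -> dict:
    """Dispatch on dataset type (CellExpression or BulkStudy)."""
    if isinstance(dataset, CellExpression):
        return write_cell_fixtures(dataset, out_dir, truth)
    if isinstance(dataset, BulkStudy):
        return write_bulk_fixtures(dataset, out_dir, truth)
    raise TypeError(f"cannot write fixtures for {type(dataset).__name__}")


def write_gmt(gene_set: GeneSet, path: PathLike, description: str = "") -> None:
    line = "\t".join([gene_set.name, description, *gene_set.members])
    Path(path).write_text(line + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _validate_counts(arr: np.ndarray) -> np.ndarray:
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return arr.astype(np.int64)


def _attach_meta(
    counts: pd.DataFrame, meta_path: PathLike, mito_prefix: str
) -> CellExpression:
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = counts.index.difference(meta.index)
    if len(missing) > 0:
        raise ValueError(
            f"metadata missing {len(missing)} cell ids (e.g. {missing[0]!r})"
        )
    extra = meta.index.difference(counts.index)
    if len(extra) > 0:
        raise ValueError(
            f"metadata has {len(extra)} cell ids absent from the matrix"
        )
    meta = meta.loc[counts.index]
    return CellExpression(counts=counts, cell_meta=meta).annotate_qc_metrics(
        mito_prefix=mito_prefix
    )


def load_matrix(
    mtx: PathLike,
    genes: PathLike,
    cells: PathLike,
    meta: PathLike,
    mito_prefix: str = "MT-",
) -> CellExpression:
    """Load an MTX triplet (genes x cells) + metadata into a CellExpression."""
    mat = scipy.io.mmread(str(mtx))
    arr = _validate_counts(np.asarray(scipy.sparse.csr_matrix(mat).todense()))
    gene_ids = Path(genes).read_text().split()
    cell_ids = Path(cells).read_text().split()
    if arr.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {arr.shape} does not match "
            f"{len(gene_ids)} genes x {len(cell_ids)} cells"
        )
    counts = pd.DataFrame(
        arr.T, index=pd.Index(cell_ids, name="cell"), columns=pd.Index(gene_ids, name="gene")
    )
    return _attach_meta(counts, meta, mito_prefix)


def load_dense(
    tsv: PathLike, meta: PathLike, mito_prefix: str = "MT-"
) -> CellExpression:
    """Load a dense cells x genes TSV (header = gene ids, index = cell ids)."""
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    arr = _validate_counts(df.to_numpy(dtype=float))
    counts = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return _attach_meta(counts, meta, mito_prefix)


def load_bulk(
    expr: PathLike,
    labels: PathLike,
    case_label: str = "sepsis",
    control_label: str = "control",
) -> BulkStudy:
    e = pd.read_csv(expr, sep="\t", index_col=0)
    lab = pd.read_csv(labels, sep="\t", index_col=0).iloc[:, 0]
    if set(e.index) != set(lab.index):
        raise ValueError("bulk expression and label sample ids do not match")
    lab = lab.loc[e.index]
    return BulkStudy(
        expr=e, labels=lab, case_label=case_label, control_label=control_label
    )


def read_gene_set(path: PathLike, name: Optional[str] = None) -> GeneSet:
    """Read a gene set from a newline list or a (first-record) GMT file."""
    text = Path(path).read_text().strip()
    first = text.splitlines()[0]
    if "\t" in first:  # GMT record: name, description, members...
        fields = first.split("\t")
        return GeneSet(name or fields[0], tuple(fields[2:]))
    members = tuple(g for g in text.split() if g)
    return GeneSet(name or Path(path).stem, members)


def read_truth(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
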