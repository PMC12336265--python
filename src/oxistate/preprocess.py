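"""Quality control, log-normalization and highly-variable-gene selection.

QC keeps cells with mitochondrial fraction below a cap and a detected-gene
count inside an open/closed interval, then drops genes detected in too few of
the retained cells; detected counts are recomputed and the cell rule
re-checked once after gene filtering so the filter is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List

import numpy as np
import pandas as pd

from .containers import CellExpression
from .io import load_dense, load_matrix  # noqa: F401  (re-exported readers)

__all__ = [
    "QCParams",
    "qc_filter",
    "log_normalize",
    "select_hvg",
    "load_matrix",
    "load_dense",
]


@dataclass(frozen=True)
class QCParams:
    """Cell- and gene-level quality thresholds.

    A cell is kept when ``mito_fraction < max_mito_frac`` and
    ``min_genes_per_cell < detected <= max_genes_per_cell``; a gene is kept
    when detected in at least ``min_cells_per_gene`` retained cells.
    """

    max_mito_frac: float = 0.20
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 7000
    min_cells_per_gene: int = 3
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not (0 < self.max_mito_frac <= 1):
            raise ValueError("max_mito_frac must be in (0, 1]")
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
        if self.min_cells_per_gene < 1:
            raise ValueError("min_cells_per_gene must be >= 1")


def _cell_mask(counts: np.ndarray, mito: np.ndarray, p: QCParams) -> np.ndarray:
    detected = (counts > 0).sum(axis=1)
    return (
        (mito < p.max_mito_frac)
        & (detected > p.min_genes_per_cell)
        & (detected <= p.max_genes_per_cell)
    )


def qc_filter(x: CellExpression, p: QCParams = QCParams()) -> CellExpression:
    """Apply cell then gene filters; attaches a removal report.

    Filter order: cells first (mito fraction + detected-gene bounds), then
    genes (detected in >= ``min_cells_per_gene`` retained cells), then one
    re-check of the cell rule on the reduced gene panel.
    """
    x = x.annotate_qc_metrics(mito_prefix=p.mito_prefix)
    counts = x.counts.to_numpy()
    mito = x.cell_meta["mito_fraction"].to_numpy()

    keep_cells = _cell_mask(counts, mito, p)
    n_cells_removed = int((~keep_cells).sum())

    sub = counts[keep_cells]
    keep_genes = (sub > 0).sum(axis=0) >= p.min_cells_per_gene
    n_genes_removed = int((~keep_genes).sum())

    sub = sub[:, keep_genes]
    recheck = _cell_mask(sub, mito[keep_cells], p)
    n_cells_recheck = int((~recheck).sum())

    cell_idx = x.cell_ids[keep_cells][recheck]
    gene_idx = x.gene_ids[keep_genes]
    if len(cell_idx) == 0:
        raise ValueError(
            "QC removed every cell "
            f"(cells failing thresholds: {n_cells_removed}; check max_mito_frac "
            f"and the detected-gene bounds)"
        )
    out = x.subset(cells=cell_idx, genes=gene_idx)
    out = out.annotate_qc_metrics(mito_prefix=p.mito_prefix)
    out.qc_report = {
        "cells_in": x.n_cells,
        "genes_in": x.n_genes,
        "cells_removed": n_cells_removed,
        "genes_removed": n_genes_removed,
        "cells_removed_recheck": n_cells_recheck,
        "cells_out": out.n_cells,
        "genes_out": out.n_genes,
    }
    return out


def log_normalize(
    x: CellExpression, scale_factor: float = 10_000.0
) -> CellExpression:
    """Library-size log-normalization: ``ln(1 + count / total * scale_factor)``."""
    counts = x.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = x.cell_ids[totals[:, 0] == 0]
        raise ValueError(f"{len(bad)} cells have zero total count (e.g. {bad[0]!r})")
    norm = np.log1p(counts / totals * scale_factor)
    out = replace(
        x,
        normalized=pd.DataFrame(norm, index=x.cell_ids, columns=x.gene_ids),
    )
    return out


def select_hvg(x: CellExpression, n: int = 3000, n_bins: int = 20) -> List[str]:
    """Top-``n`` highly variable genes by binned standardized dispersion.

    Dispersion = variance / mean of normalized expression per gene, z-scored
    within ``n_bins`` equal-occupancy mean bins.  Constant (or all-zero)
    genes have undefined dispersion and rank last.  Ties break on gene id so
    the selected set is invariant to input gene order.
    """
    if x.normalized is None:
        raise ValueError("normalized layer missing; run log_normalize first")
    if x.n_cells < 2:
        raise ValueError("need at least 2 cells for dispersion estimates")
    norm = x.normalized.to_numpy()
    mean = norm.mean(axis=0)
    var = norm.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, np.nan)
    disp[var == 0] = np.nan

    ok = ~np.isnan(disp)
    z = np.full(x.n_genes, -np.inf)
    if ok.sum() > 0:
        n_ok = int(ok.sum())
        bins = min(n_bins, n_ok)
        # equal-occupancy bins over gene means (rank-based)
        order = np.argsort(mean[ok], kind="stable")
        bin_id = np.empty(n_ok, dtype=int)
        bin_id[order] = np.minimum((np.arange(n_ok) * bins) // n_ok, bins - 1)
        zz = np.empty(n_ok)
        d = disp[ok]
        for b in range(bins):
            m = bin_id == b
            mu, sd = d[m].mean(), d[m].std(ddof=1) if m.sum() > 1 else 0.0
            zz[m] = (d[m] - mu) / sd if sd > 0 else 0.0
        z[ok] = zz

    order = sorted(
        range(x.n_genes), key=lambda i: (-z[i], x.gene_ids[i])
    )
    selected = [x.gene_ids[i] for i in order if np.isfinite(z[i])][: min(n, x.n_genes)]
    if len(selected) < min(n, x.n_genes):
        warnings.warn(
            "fewer non-constant genes than requested HVGs; returning all "
            f"{len(selected)}"
        )
    return selected
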