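"""Core in-memory containers shared across pipeline stages.

The single-cell container keeps the raw counts and (once computed) the
log-normalized matrix as cells x genes :class:`pandas.DataFrame` objects with
aligned per-cell metadata.  At the scale this package targets (thousands to a
few hundred thousand cells after down-sampling) dense frames are simple and
fast; ``to_anndata`` is provided for interop with the scanpy ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["CellExpression", "GeneSet", "BulkStudy"]


@dataclass
class CellExpression:
    """Single-cell expression: counts, optional normalized layer, metadata.

    Parameters
    ----------
    counts
        cells x genes non-negative integer matrix.  Row index = cell ids,
        column index = gene ids (unique).
    cell_meta
        Per-cell table indexed by cell id.  Standard columns: ``sample``,
        ``condition`` and optionally ``cell_type``; QC columns
        ``detected_gene_count`` and ``mito_fraction`` are added by the
        loaders / generator.
    normalized
        cells x genes real matrix, present after :func:`log_normalize`.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame
    normalized: Optional[pd.DataFrame] = None
    qc_report: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.cell_meta.index):
            raise ValueError("counts rows and cell_meta index must match")
        if self.counts.columns.has_duplicates:
            raise ValueError("gene ids must be unique")
        if self.normalized is not None:
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized layer shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.columns

    def annotate_qc_metrics(self, mito_prefix: str = "MT-") -> "CellExpression":
        """Compute per-cell detected-gene count and mitochondrial fraction."""
        c = self.counts.to_numpy()
        meta = self.cell_meta.copy()
        meta["detected_gene_count"] = (c > 0).sum(axis=1)
        is_mito = self.gene_ids.str.startswith(mito_prefix)
        total = c.sum(axis=1)
        mito = c[:, np.asarray(is_mito)].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        meta["mito_fraction"] = frac
        return replace(self, cell_meta=meta)

    def subset(
        self,
        cells: Optional[Iterable] = None,
        genes: Optional[Iterable] = None,
    ) -> "CellExpression":
        counts = self.counts
        meta = self.cell_meta
        norm = self.normalized
        if cells is not None:
            cells = pd.Index(cells)
            counts = counts.loc[cells]
            meta = meta.loc[cells]
            if norm is not None:
                norm = norm.loc[cells]
        if genes is not None:
            genes = pd.Index(genes)
            counts = counts[genes]
            if norm is not None:
                norm = norm[genes]
        return CellExpression(counts=counts, cell_meta=meta, normalized=norm)

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (counts in ``layers['counts']``)."""
        import anndata as ad

        x = self.normalized if self.normalized is not None else self.counts
        adata = ad.AnnData(
            X=x.to_numpy(dtype=float),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.layers["counts"] = self.counts.to_numpy()
        return adata


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free gene list (e.g. the oxidative-stress signature)."""

    name: str
    members: tuple

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if len(members) == 0:
            raise ValueError("gene set must be nonempty")
        if len(set(members)) != len(members):
            raise ValueError("gene set contains duplicate ids")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def intersect(self, gene_ids: Iterable) -> "GeneSet":
        present = [g for g in self.members if g in set(gene_ids)]
        if not present:
            raise ValueError(
                f"no member of gene set {self.name!r} found in the matrix"
            )
        return GeneSet(self.name, tuple(present))


@dataclass
class BulkStudy:
    """Bulk cohort: samples x genes log-scale expression with binary labels."""

    expr: pd.DataFrame
    labels: pd.Series
    case_label: str = "sepsis"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.labels.index):
            raise ValueError("expression rows and labels index must match")
        observed = set(self.labels.unique())
        if not observed <= {self.case_label, self.control_label}:
            raise ValueError(f"unexpected labels: {observed}")

    @property
    def is_case(self) -> np.ndarray:
        return (self.labels == self.case_label).to_numpy()

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())
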