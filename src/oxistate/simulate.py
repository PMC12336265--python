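"""Synthetic single-cell and bulk cohorts with known ground truth.

The generator emulates the structure of a multi-sample sepsis single-cell
study plus a case/control bulk cohort:

* counts follow a negative-binomial model with lognormal gene means scaled to
  each cell's library size;
* a planted oxidative-stress (OS) program: a designated gene set of which a
  "responsive" subset is boosted ``2**effect_log2fc``-fold in a fraction of
  "active" cells, preferentially placed in the early-sepsis condition;
* planted co-expression modules: gene blocks sharing a per-cell latent
  Gaussian factor on the log-mean scale;
* mitochondrial genes (``MT-`` prefix) whose counts are inflated per cell to
  a drawn mitochondrial fraction, so QC filtering can be exercised;
* a bulk cohort on the same gene universe in which planted hub genes are
  shifted up in cases by a standardized effect.

Everything is a pure function of the :class:`SimConfig` (including its seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .containers import BulkStudy, CellExpression, GeneSet

__all__ = [
    "SimConfig",
    "SimTruth",
    "make_gene_set",
    "simulate_cells",
    "simulate_bulk",
    "simulate_study",
]

CONDITIONS = ("control", "early_sepsis", "late_sepsis")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define the reference desk-scale study: 2,000 cells x 2,000
    genes, a 400-gene OS set with 200 responsive genes boosted two-fold in
    25% of cells (active cells enriched in early sepsis), three background
    co-expression modules of sizes 60/60/40, and a 60 vs 60 bulk cohort with
    5 hub genes shifted by 1.5 SD in cases.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    condition_props: Mapping[str, float] = field(
        default_factory=lambda: {
            "control": 1 / 3,
            "early_sepsis": 1 / 3,
            "late_sepsis": 1 / 3,
        }
    )
    n_samples_per_condition: int = 2
    n_cell_types: int = 5
    os_set_size: int = 400
    os_responsive_size: int = 200
    active_fraction: float = 0.25
    active_condition_bias: float = 0.7
    effect_log2fc: float = 1.0
    nb_dispersion: float = 0.5
    libsize_range: Tuple[float, float] = (1000.0, 5000.0)
    mito_beta: Tuple[float, float] = (2.0, 20.0)
    mito_gene_fraction: float = 0.01
    n_modules: int = 3
    module_size: Tuple[int, ...] | int = (60, 60, 40)
    module_loading: float = 0.8
    bulk_n_case: int = 60
    bulk_n_control: int = 60
    bulk_n_genes: int = 300
    n_informative_bulk: int = 5
    bulk_hub_effect: float = 1.5
    bulk_os_effect: float = 0.3
    bulk_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cells",
            "n_genes",
            "n_cell_types",
            "os_set_size",
            "n_modules",
            "bulk_n_case",
            "bulk_n_control",
            "bulk_n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        props = dict(self.condition_props)
        if set(props) != set(CONDITIONS):
            raise ValueError(f"condition_props must cover {CONDITIONS}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("condition_props must sum to 1")
        if not (0 < self.active_fraction < 1):
            raise ValueError("active_fraction must be in (0, 1)")
        if not (0 <= self.active_condition_bias <= 1):
            raise ValueError("active_condition_bias must be in [0, 1]")
        if self.os_responsive_size > self.os_set_size:
            raise ValueError("os_responsive_size must not exceed os_set_size")
        if self.os_set_size > self.n_genes:
            raise ValueError("os_set_size must not exceed n_genes")
        lo, hi = self.libsize_range
        if not lo < hi:
            raise ValueError("libsize_range must satisfy min < max")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_informative_bulk == 0 and self.bulk_hub_effect != 0:
            raise ValueError(
                "bulk_hub_effect is nonzero but no informative bulk genes requested"
            )

    @property
    def module_sizes(self) -> Tuple[int, ...]:
        if isinstance(self.module_size, int):
            return (self.module_size,) * self.n_modules
        sizes = tuple(self.module_size)
        if len(sizes) != self.n_modules:
            raise ValueError("module_size tuple length must equal n_modules")
        return sizes

    @property
    def n_mito_genes(self) -> int:
        return math.ceil(self.mito_gene_fraction * self.n_genes)


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    active_cells: pd.Series  # boolean, indexed by cell id
    responsive_genes: list
    module_membership: dict  # gene id -> "M1".."Mk"
    informative_bulk_genes: list

    def to_dict(self) -> dict:
        return {
            "active_cells": list(self.active_cells.index[self.active_cells]),
            "responsive_genes": list(self.responsive_genes),
            "module_membership": dict(self.module_membership),
            "informative_bulk_genes": list(self.informative_bulk_genes),
        }


# ---------------------------------------------------------------------------
# gene universe layout (deterministic, seed-free)
# ---------------------------------------------------------------------------


def _gene_universe(cfg: SimConfig) -> pd.Index:
    n_mito = cfg.n_mito_genes
    names = [f"MT-{i + 1:04d}" for i in range(n_mito)]
    names += [f"G{i + 1:05d}" for i in range(cfg.n_genes - n_mito)]
    return pd.Index(names, name="gene")


def _layout(cfg: SimConfig):
    """Assign fixed index blocks: mito | OS set | modules | background."""
    genes = _gene_universe(cfg)
    n_mito = cfg.n_mito_genes
    os_idx = np.arange(n_mito, n_mito + cfg.os_set_size)
    pos = n_mito + cfg.os_set_size
    module_idx = []
    for size in cfg.module_sizes:
        if pos + size > cfg.n_genes:
            raise ValueError("gene universe too small for requested modules")
        module_idx.append(np.arange(pos, pos + size))
        pos += size
    return genes, os_idx, module_idx


def make_gene_set(cfg: SimConfig) -> Tuple[GeneSet, list]:
    """The synthetic OS gene set and its responsive subset.

    Returns the named set of ``os_set_size`` unique gene ids and the list of
    ``os_responsive_size`` responsive members (the genes actually boosted in
    active cells).
    """
    genes, os_idx, _ = _layout(cfg)
    members = tuple(genes[os_idx])
    responsive = list(members[: cfg.os_responsive_size])
    return GeneSet("synthetic_os", members), responsive


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------


def _assign_conditions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    props = np.array([cfg.condition_props[c] for c in CONDITIONS])
    counts = np.floor(props * cfg.n_cells).astype(int)
    # distribute the rounding remainder deterministically
    for i in range(cfg.n_cells - counts.sum()):
        counts[i % len(CONDITIONS)] += 1
    cond = np.repeat(np.arange(len(CONDITIONS)), counts)
    rng.shuffle(cond)
    return cond


def _assign_active(
    cfg: SimConfig, cond: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n_active = int(round(cfg.active_fraction * cfg.n_cells))
    early = np.flatnonzero(cond == CONDITIONS.index("early_sepsis"))
    other = np.flatnonzero(cond != CONDITIONS.index("early_sepsis"))
    n_early = min(int(round(cfg.active_condition_bias * n_active)), early.size)
    n_other = min(n_active - n_early, other.size)
    chosen = np.concatenate(
        [
            rng.choice(early, size=n_early, replace=False),
            rng.choice(other, size=n_other, replace=False),
        ]
    )
    active = np.zeros(cfg.n_cells, dtype=bool)
    active[chosen] = True
    return active


def simulate_cells(cfg: SimConfig) -> Tuple[CellExpression, SimTruth]:
    """Draw the single-cell count matrix and its ground truth.

    Counts are negative-binomial with mean ``libsize_c * p_g`` where the gene
    weights ``p_g`` come from lognormal base means (log-mean -1, log-sd 1)
    perturbed per cell by the planted module factors; active cells then get a
    ``2**effect_log2fc`` multiplicative boost on responsive genes, and
    mitochondrial genes are scaled to the drawn per-cell mito fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, os_idx, module_idx = _layout(cfg)
    n_cells, n_genes = cfg.n_cells, cfg.n_genes
    n_mito = cfg.n_mito_genes

    cond = _assign_conditions(cfg, rng)
    sample_rep = rng.integers(cfg.n_samples_per_condition, size=n_cells)
    cell_type = rng.integers(cfg.n_cell_types, size=n_cells)
    active = _assign_active(cfg, cond, rng)

    base_log_mu = rng.normal(-1.0, 1.0, size=n_genes)
    log_mu = np.tile(base_log_mu, (n_cells, 1))
    for m, idx in enumerate(module_idx):
        z = rng.normal(0.0, 1.0, size=n_cells)
        log_mu[:, idx] += cfg.module_loading * z[:, None]

    weights = np.exp(log_mu)
    libsize = rng.uniform(*cfg.libsize_range, size=n_cells)
    mito_frac = rng.beta(*cfg.mito_beta, size=n_cells)

    mu = np.empty_like(weights)
    nonmito = weights[:, n_mito:]
    mu[:, n_mito:] = (
        nonmito
        / nonmito.sum(axis=1, keepdims=True)
        * (libsize * (1.0 - mito_frac))[:, None]
    )
    mito_w = weights[:, :n_mito]
    mu[:, :n_mito] = (
        mito_w / mito_w.sum(axis=1, keepdims=True) * (libsize * mito_frac)[:, None]
    )

    resp_idx = os_idx[: cfg.os_responsive_size]
    if cfg.effect_log2fc != 0:
        mu[np.ix_(active, resp_idx)] *= 2.0 ** cfg.effect_log2fc

    size = 1.0 / cfg.nb_dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    cell_ids = pd.Index([f"cell{i + 1:05d}" for i in range(n_cells)], name="cell")
    meta = pd.DataFrame(
        {
            "sample": [
                f"{CONDITIONS[c]}_s{r + 1}" for c, r in zip(cond, sample_rep)
            ],
            "condition": [CONDITIONS[c] for c in cond],
            "cell_type": [f"type{t + 1}" for t in cell_type],
        },
        index=cell_ids,
    )
    x = CellExpression(
        counts=pd.DataFrame(counts, index=cell_ids, columns=genes),
        cell_meta=meta,
    ).annotate_qc_metrics()

    membership = {}
    for m, idx in enumerate(module_idx):
        for g in genes[idx]:
            membership[g] = f"M{m + 1}"
    os_set, responsive = make_gene_set(cfg)
    truth = SimTruth(
        active_cells=pd.Series(active, index=cell_ids, name="active"),
        responsive_genes=responsive,
        module_membership=membership,
        informative_bulk_genes=_informative_bulk(cfg),
    )
    return x, truth


# ---------------------------------------------------------------------------
# bulk simulation
# ---------------------------------------------------------------------------


def _informative_bulk(cfg: SimConfig) -> list:
    _, responsive = make_gene_set(cfg)
    return responsive[: cfg.n_informative_bulk]


def _bulk_genes(cfg: SimConfig) -> Tuple[pd.Index, np.ndarray, np.ndarray]:
    """Bulk gene universe: half from the OS set (hub genes first), half filler.

    Returns (gene index, informative mask, os-member mask).
    """
    genes, os_idx, module_idx = _layout(cfg)
    os_genes = list(genes[os_idx])
    n_os_in_bulk = min(len(os_genes), cfg.bulk_n_genes // 2)
    chosen = os_genes[:n_os_in_bulk]
    # filler: background genes not in the OS set, after the module blocks
    start = os_idx[-1] + 1 + sum(cfg.module_sizes)
    filler = list(genes[start:])
    need = cfg.bulk_n_genes - n_os_in_bulk
    if need > len(filler):
        raise ValueError("gene universe too small for requested bulk_n_genes")
    chosen += filler[:need]
    idx = pd.Index(chosen, name="gene")
    informative = set(_informative_bulk(cfg))
    info_mask = idx.isin(informative)
    os_mask = idx.isin(os_genes)
    return idx, np.asarray(info_mask), np.asarray(os_mask)


def simulate_bulk(cfg: SimConfig) -> Tuple[BulkStudy, list]:
    """Draw the bulk case/control cohort.

    Log-scale expression is Gaussian around gene baselines; planted hub genes
    are shifted up by ``bulk_hub_effect`` standard deviations in cases and the
    remaining OS-set genes by ``bulk_os_effect`` (the cohort-level elevation
    of the OS program in disease).  Returns the study and the list of planted
    informative genes.
    """
    if cfg.bulk_n_case < 2 or cfg.bulk_n_control < 2:
        raise ValueError("bulk cohort needs at least 2 samples per class")
    rng = np.random.default_rng((cfg.seed, 0xB0_1D))
    genes, info_mask, os_mask = _bulk_genes(cfg)
    n = cfg.bulk_n_case + cfg.bulk_n_control
    baseline = rng.normal(7.0, 2.0, size=len(genes))
    expr = rng.normal(0.0, cfg.bulk_noise_sd, size=(n, len(genes))) + baseline

    is_case = np.zeros(n, dtype=bool)
    is_case[: cfg.bulk_n_case] = True
    shift = np.zeros(len(genes))
    shift[info_mask] = cfg.bulk_hub_effect * cfg.bulk_noise_sd
    shift[os_mask & ~info_mask] = cfg.bulk_os_effect * cfg.bulk_noise_sd
    expr[is_case] += shift

    sample_ids = pd.Index(
        [f"case{i + 1:03d}" for i in range(cfg.bulk_n_case)]
        + [f"ctrl{i + 1:03d}" for i in range(cfg.bulk_n_control)],
        name="sample",
    )
    study = BulkStudy(
        expr=pd.DataFrame(expr, index=sample_ids, columns=genes),
        labels=pd.Series(
            np.where(is_case, "sepsis", "control"), index=sample_ids, name="label"
        ),
    )
    return study, _informative_bulk(cfg)


def simulate_study(
    cfg: SimConfig,
) -> Tuple[CellExpression, BulkStudy, GeneSet, SimTruth]:
    """Generate the full paired study: cells, bulk cohort, OS set, truth."""
    cells, truth = simulate_cells(cfg)
    bulk, informative = simulate_bulk(cfg)
    truth.informative_bulk_genes = informative
    os_set, _ = make_gene_set(cfg)
    return cells, bulk, os_set, truth
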