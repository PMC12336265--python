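"""Single-sample gene-set activity scoring and the quartile state call.

Five per-cell scoring algorithms are implemented, each a self-contained
definition of "how active is this gene set in this cell":

``auc_recovery``
    Area under the early part of the set-gene recovery curve over the
    expression-ranked gene list, normalized by the maximal attainable area
    (the AUCell statistic).
``rank_u``
    A Mann-Whitney-U transform of the set genes' expression ranks, with
    ranks clipped at ``r_max`` so dropout-dominated tails carry no signal
    (the UCell statistic).
``sample_rank``
    Mean set-gene rank, min-max rescaled between its theoretical extremes
    (the singscore statistic for an up-set).
``weighted_ks``
    Weighted Kolmogorov-Smirnov running-sum enrichment integrated over the
    ranked list (the single-sample GSEA statistic), usable on any
    samples x genes real matrix including bulk cohorts.
``binned_control``
    Mean set-gene expression minus the mean of expression-matched control
    genes sampled from equal-occupancy mean-expression bins (the module-score
    statistic).

The consensus composite z-scores each method column, min-max rescales it to
[0, 1] and sums the rows; the quartile tripartition labels cells below the
25th percentile "low", above the 75th "high", and "transition" in between
(boundary ties go to transition, the inequalities being strict).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CellExpression, GeneSet

__all__ = [
    "ScorePanel",
    "METHODS",
    "score_auc_recovery",
    "score_rank_u",
    "score_sample_rank",
    "score_weighted_ks",
    "score_binned_control",
    "combine_scores",
    "assign_states",
    "score_cells",
]

METHODS = (
    "auc_recovery",
    "rank_u",
    "sample_rank",
    "weighted_ks",
    "binned_control",
)

STATES = ("low", "transition", "high")


@dataclass
class ScorePanel:
    """Per-cell scores: raw methods, normalized columns, composite, state."""

    raw: pd.DataFrame
    znorm: pd.DataFrame
    unit: pd.DataFrame
    composite: pd.Series
    state: pd.Series
    q1: float
    q3: float


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _as_matrix(x: Union[CellExpression, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(x, CellExpression):
        if x.normalized is None:
            raise ValueError("normalized layer missing; run log_normalize first")
        return x.normalized
    return x


def _set_mask(matrix: pd.DataFrame, s: GeneSet) -> np.ndarray:
    mask = matrix.columns.isin(s.members)
    n_hit = int(mask.sum())
    if n_hit == 0:
        missing = list(s.members)[:5]
        raise ValueError(
            f"no gene of set {s.name!r} present in the matrix "
            f"(first missing: {missing})"
        )
    if n_hit < len(s):
        warnings.warn(
            f"{len(s) - n_hit} of {len(s)} genes of set {s.name!r} absent "
            "from the matrix; scoring the intersection"
        )
    return np.asarray(mask)


# ---------------------------------------------------------------------------
# the five scorers
# ---------------------------------------------------------------------------


def score_auc_recovery(
    x: Union[CellExpression, pd.DataFrame],
    s: GeneSet,
    top_frac: float = 0.05,
) -> pd.Series:
    """Normalized area under the set-gene recovery curve (AUCell).

    Per cell, genes are ranked by decreasing expression (ties keep input
    order); with ``y(k)`` the number of set genes among the top ``k`` for
    ``k = 1..T`` (``T = ceil(top_frac * n_genes)``), the score is
    ``sum_k y(k) / sum_k min(k, |s|)`` and lies in [0, 1].
    """
    m = _as_matrix(x)
    mask = _set_mask(m, s)
    vals = m.to_numpy()
    n_cells, n_genes = vals.shape
    t = math.ceil(top_frac * n_genes)
    n_set = int(mask.sum())

    # position (1-based) of each gene in the per-cell decreasing order;
    # stable argsort keeps ties in input order
    order = np.argsort(-vals, axis=1, kind="stable")
    pos = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    pos[rows, order] = np.arange(1, n_genes + 1)

    set_pos = pos[:, mask]
    contrib = np.clip(t - set_pos + 1, 0, None)  # sum_k 1{pos <= k}, k<=T
    num = contrib.sum(axis=1)
    if n_set >= t:
        denom = t * (t + 1) // 2
    else:
        denom = n_set * (n_set + 1) // 2 + (t - n_set) * n_set
    return pd.Series(num / denom, index=m.index, name="auc_recovery")


def score_rank_u(
    x: Union[CellExpression, pd.DataFrame],
    s: GeneSet,
    r_max: int = 1500,
) -> pd.Series:
    """Clipped Mann-Whitney rank score (UCell).

    Per cell, genes are ranked by decreasing expression (average ranks on
    ties), set-gene ranks above ``r_max`` clipped to ``r_max + 1``; with
    ``U = sum(ranks) - |s|(|s|+1)/2`` the score is ``1 - U / (|s| r_max)``
    clipped to [0, 1].
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    m = _as_matrix(x)
    mask = _set_mask(m, s)
    vals = m.to_numpy()
    ranks = rankdata(-vals, axis=1)
    set_ranks = np.minimum(ranks[:, mask], r_max + 1)
    n_set = int(mask.sum())
    u = set_ranks.sum(axis=1) - n_set * (n_set + 1) / 2
    score = 1.0 - u / (n_set * r_max)
    return pd.Series(np.clip(score, 0.0, 1.0), index=m.index, name="rank_u")


def score_sample_rank(
    x: Union[CellExpression, pd.DataFrame], s: GeneSet
) -> pd.Series:
    """Rescaled mean set-gene rank (singscore, up-set).

    Ranks by increasing expression (average ties); the mean set rank is
    rescaled between its minimum ``(|s|+1)/2`` and maximum
    ``n_genes - (|s|-1)/2``.
    """
    m = _as_matrix(x)
    mask = _set_mask(m, s)
    n_set = int(mask.sum())
    n_genes = m.shape[1]
    if n_set == n_genes:
        raise ValueError(
            "gene set covers the whole matrix; mean-rank score is degenerate"
        )
    ranks = rankdata(m.to_numpy(), axis=1)
    mr = ranks[:, mask].mean(axis=1)
    mr_min = (n_set + 1) / 2
    mr_max = n_genes - (n_set - 1) / 2
    return pd.Series(
        (mr - mr_min) / (mr_max - mr_min), index=m.index, name="sample_rank"
    )


def score_weighted_ks(
    x: Union[CellExpression, pd.DataFrame],
    s: GeneSet,
    alpha: float = 0.25,
) -> pd.Series:
    """Weighted KS running-sum enrichment (single-sample GSEA).

    Walking down the per-sample decreasing-expression ordering, the inside
    CDF weights set genes by ``(n_genes - position + 1) ** alpha`` and the
    outside CDF counts non-set genes; the score is the running-sum difference
    summed over all positions, divided by ``n_genes``.
    """
    m = _as_matrix(x)
    mask = _set_mask(m, s)
    vals = m.to_numpy()
    n_samples, n_genes = vals.shape
    n_set = int(mask.sum())

    order = np.argsort(-vals, axis=1, kind="stable")
    in_set = mask[order]  # sample x position membership
    w = (n_genes - np.arange(n_genes)).astype(float) ** alpha  # rank-from-top weight

    win = np.where(in_set, w[None, :], 0.0)
    p_in = np.cumsum(win, axis=1) / win.sum(axis=1, keepdims=True)
    p_out = np.cumsum(~in_set, axis=1) / (n_genes - n_set)
    score = (p_in - p_out).sum(axis=1) / n_genes
    return pd.Series(score, index=m.index, name="weighted_ks")


def score_binned_control(
    x: Union[CellExpression, pd.DataFrame],
    s: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-matched control score (module score).

    Genes are placed in ``n_bins`` equal-occupancy bins by mean expression
    across cells; each set gene draws ``n_ctrl`` control genes (with
    replacement, seeded) from its bin; the score is the per-cell mean over
    set genes minus the mean over the pooled control draws.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    m = _as_matrix(x)
    mask = _set_mask(m, s)
    vals = m.to_numpy()
    n_genes = vals.shape[1]
    if n_bins > n_genes:
        warnings.warn(
            f"n_bins={n_bins} exceeds the {n_genes}-gene universe; "
            f"rebinning with {n_genes} bins"
        )
        n_bins = n_genes

    mean = vals.mean(axis=0)
    order = np.argsort(mean, kind="stable")
    bin_id = np.empty(n_genes, dtype=int)
    bin_id[order] = np.minimum((np.arange(n_genes) * n_bins) // n_genes, n_bins - 1)

    rng = np.random.default_rng(seed)
    set_idx = np.flatnonzero(mask)
    ctrl_idx = []
    for g in set_idx:
        pool = np.flatnonzero(bin_id == bin_id[g])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)

    score = vals[:, set_idx].mean(axis=1) - vals[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=m.index, name="binned_control")


# ---------------------------------------------------------------------------
# consensus and states
# ---------------------------------------------------------------------------


def combine_scores(raw: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Column-wise z-score then min-max to [0,1]; composite = row sum.

    A constant column contributes zero to every cell (with a warning).
    Returns ``(znorm, unit, composite)``.
    """
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 cells to standardize score columns")
    if raw.shape[1] < 1:
        raise ValueError("need at least one method column")
    vals = raw.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant score column(s) contribute 0: "
            f"{list(raw.columns[constant])}"
        )
    z = np.zeros_like(vals)
    z[:, ~constant] = (vals[:, ~constant] - mean[~constant]) / sd[~constant]
    zmin, zmax = z.min(axis=0), z.max(axis=0)
    rng_ = np.where(zmax > zmin, zmax - zmin, 1.0)
    unit = (z - zmin) / rng_
    unit[:, constant] = 0.0
    znorm = pd.DataFrame(z, index=raw.index, columns=raw.columns)
    unit_df = pd.DataFrame(unit, index=raw.index, columns=raw.columns)
    composite = pd.Series(unit.sum(axis=1), index=raw.index, name="composite")
    return znorm, unit_df, composite


def assign_states(
    composite: Union[pd.Series, np.ndarray]
) -> Tuple[pd.Series, float, float]:
    """Quartile tripartition of the composite score.

    ``q1``/``q3`` are the 25th/75th percentiles (linear interpolation between
    order statistics); a cell is ``low`` iff score < q1, ``high`` iff score
    > q3, else ``transition`` (boundary ties are transition).
    """
    values = np.asarray(composite, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 cells for quartile states")
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    labels = np.full(values.shape, "transition", dtype=object)
    labels[values < q1] = "low"
    labels[values > q3] = "high"
    index = composite.index if isinstance(composite, pd.Series) else None
    return (
        pd.Series(pd.Categorical(labels, categories=STATES), index=index, name="state"),
        float(q1),
        float(q3),
    )


def score_cells(
    x: Union[CellExpression, pd.DataFrame],
    s: GeneSet,
    methods: Sequence[str] = METHODS,
    seed: int = 0,
    top_frac: float = 0.05,
    r_max: int = 1500,
    alpha: float = 0.25,
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> ScorePanel:
    """Run the requested scorers, build the consensus and assign states."""
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown scoring methods: {sorted(unknown)}")
    cols = {}
    for method in methods:
        if method == "auc_recovery":
            cols[method] = score_auc_recovery(x, s, top_frac=top_frac)
        elif method == "rank_u":
            cols[method] = score_rank_u(x, s, r_max=r_max)
        elif method == "sample_rank":
            cols[method] = score_sample_rank(x, s)
        elif method == "weighted_ks":
            cols[method] = score_weighted_ks(x, s, alpha=alpha)
        elif method == "binned_control":
            cols[method] = score_binned_control(
                x, s, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
            )
    raw = pd.DataFrame(cols)
    znorm, unit, composite = combine_scores(raw)
    state, q1, q3 = assign_states(composite)
    return ScorePanel(
        raw=raw, znorm=znorm, unit=unit, composite=composite,
        state=state, q1=q1, q3=q3,
    )
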