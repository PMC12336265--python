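"""Bulk-cohort validation of hub genes.

Three read-outs per hub gene on a labeled case/control cohort: a two-sided
Wilcoxon rank-sum group difference with BH q-values, the ROC AUC of the gene
as a univariate diagnostic score (Mann-Whitney pair-concordance definition,
ties half-weighted), and Pearson + Spearman correlation with the per-sample
OS signature score (weighted-KS enrichment of the OS set on the bulk
matrix).
"""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .containers import BulkStudy, GeneSet
from .scoring import score_weighted_ks
from .state_analysis import rank_sum_test

__all__ = [
    "group_difference",
    "roc_auc",
    "roc_curve_points",
    "correlate_with_score",
    "validate_hub_genes",
]


def group_difference(b: BulkStudy, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum case vs control, BH-adjusted."""
    is_case = b.is_case
    if is_case.sum() < 3 or (~is_case).sum() < 3:
        raise ValueError("need >= 3 samples per class")
    present = [g for g in genes if g in b.expr.columns]
    skipped = [g for g in genes if g not in b.expr.columns]
    if skipped:
        warnings.warn(f"{len(skipped)} gene(s) absent from the bulk panel: skipped")
    if not present:
        raise ValueError("no requested gene present in the bulk panel")
    vals = b.expr[present].to_numpy()
    p = rank_sum_test(vals[is_case], vals[~is_case])
    diff = vals[is_case].mean(axis=0) - vals[~is_case].mean(axis=0)
    out = pd.DataFrame(
        {
            "mean_difference": diff,
            "direction": np.where(diff > 0, "up_in_case", "down_in_case"),
            "p_value": p,
            "q_value": multipletests(p, method="fdr_bh")[1],
        },
        index=pd.Index(present, name="gene"),
    )
    return out


def roc_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC = (concordant + 0.5 * tied pairs) / (n_case * n_control).

    ``labels`` is boolean (True = case).  Computed via the rank identity
    with average ranks, which half-weights ties exactly.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("labels contain a single class")
    ranks = rankdata(values)
    u = ranks[labels].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


def roc_curve_points(
    values: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """ROC curve (FPR, TPR) at every distinct threshold, descending."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-values, kind="stable")
    lab = labels[order]
    tp = np.cumsum(lab)
    fp = np.cumsum(~lab)
    # collapse ties: keep the last point of each run of equal values
    v = values[order]
    last = np.r_[v[1:] != v[:-1], True]
    tpr = np.r_[0.0, tp[last] / labels.sum()]
    fpr = np.r_[0.0, fp[last] / (~labels).sum()]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def correlate_with_score(
    b: BulkStudy,
    genes: Sequence[str],
    os_set: GeneSet,
    alpha: float = 0.25,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Correlate each gene with the per-sample OS enrichment score.

    The OS score is the weighted-KS statistic of the OS set on the bulk
    matrix.  Returns the per-gene correlation table and the score vector.
    """
    os_present = os_set.intersect(b.expr.columns)
    score = score_weighted_ks(b.expr, os_present, alpha=alpha)
    rows = []
    for g in genes:
        if g not in b.expr.columns:
            warnings.warn(f"gene {g!r} absent from the bulk panel: skipped")
            continue
        v = b.expr[g].to_numpy()
        if np.ptp(v) == 0:
            rows.append(
                {
                    "gene": g,
                    "pearson_r": np.nan,
                    "pearson_p": np.nan,
                    "spearman_r": np.nan,
                    "spearman_p": np.nan,
                    "constant": True,
                }
            )
            continue
        pr = pearsonr(v, score.to_numpy())
        sr = spearmanr(v, score.to_numpy())
        rows.append(
            {
                "gene": g,
                "pearson_r": float(pr.statistic),
                "pearson_p": float(pr.pvalue),
                "spearman_r": float(sr.statistic),
                "spearman_p": float(sr.pvalue),
                "constant": False,
            }
        )
    if not rows:
        raise ValueError("no requested gene present in the bulk panel")
    return pd.DataFrame(rows).set_index("gene"), score.rename("os_score")


def validate_hub_genes(
    b: BulkStudy, genes: Sequence[str], os_set: GeneSet
) -> Tuple[pd.DataFrame, pd.Series]:
    """Full per-gene validation table: difference test, AUC, correlations."""
    stats = group_difference(b, genes)
    cors, os_score = correlate_with_score(b, list(stats.index), os_set)
    aucs = pd.Series(
        {g: roc_auc(b.expr[g].to_numpy(), b.is_case) for g in stats.index},
        name="auc",
    )
    table = stats.join(aucs).join(cors)
    return table, os_score
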