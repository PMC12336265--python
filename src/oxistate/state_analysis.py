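"""Differential expression between OS states and state-composition tests.

Differential expression follows the standard single-cell marker-test recipe:
a two-sided Wilcoxon rank-sum test per gene on log-normalized expression
(normal approximation with tie and continuity correction), a fold change
computed on the exponentiated scale with a +1 pseudocount, Bonferroni
adjustment by default, and the strict pass filter ``avg_log2FC > 0.25`` and
``p_adj < 0.05``.

Composition testing asks, per cell type, whether that type's cells are
distributed across the low/transition/high states differently from all other
cells: a chi-squared test of independence on the 2x3 table, falling back to
an exact (Fisher-Freeman-Halton style) test when any expected count is
below 5, with Benjamini-Hochberg q-values across cell types.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, norm, rankdata, random_table
from statsmodels.stats.multitest import multipletests

from .containers import CellExpression
from .scoring import STATES

__all__ = [
    "differential_expression",
    "composition_test",
    "rank_sum_test",
]


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum tests, columns of ``a`` vs ``b``.

    Normal approximation with tie correction and continuity correction;
    inputs are (n_a x g) and (n_b x g) matrices, output is g p-values.
    """
    n1, n2 = a.shape[0], b.shape[0]
    combined = np.vstack([a, b])
    ranks = rankdata(combined, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per column
    tie_term = np.zeros(a.shape[1])
    for j in range(a.shape[1]):
        _, counts = np.unique(combined[:, j], return_counts=True)
        t = counts[counts > 1]
        if t.size:
            tie_term[j] = (t**3 - t).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mu) - 0.5) / sigma
    z = np.where(sigma > 0, np.clip(z, 0, None), 0.0)
    p = 2.0 * norm.sf(z)
    return np.minimum(p, 1.0)


def differential_expression(
    x: CellExpression,
    states: pd.Series,
    group_a: str = "high",
    group_b: str = "low",
    min_log2fc: float = 0.25,
    alpha: float = 0.05,
    min_pct: float = 0.10,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-gene Wilcoxon DE between two state groups with strict pass filter.

    Genes detected in fewer than ``min_pct`` of cells in both groups are not
    tested.  Returns a table with ``avg_log2FC``, ``p_value``, ``p_adj``,
    detection fractions and the boolean ``passes`` flag, sorted by p then by
    decreasing fold change.
    """
    if x.normalized is None:
        raise ValueError("normalized layer missing; run log_normalize first")
    states = states.loc[x.cell_ids]
    in_a = (states == group_a).to_numpy()
    in_b = (states == group_b).to_numpy()
    if in_a.sum() < 3 or in_b.sum() < 3:
        raise ValueError(
            f"each group needs >= 3 cells (got {in_a.sum()} {group_a!r}, "
            f"{in_b.sum()} {group_b!r})"
        )
    norm_ = x.normalized.to_numpy()
    a = norm_[in_a]
    b = norm_[in_b]
    pct_a = (a > 0).mean(axis=0)
    pct_b = (b > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)
    if not tested.any():
        raise ValueError("no gene passes the detection filter")

    p = rank_sum_test(a[:, tested], b[:, tested])
    if adjust == "bonferroni":
        p_adj = np.minimum(p * tested.sum(), 1.0)
    elif adjust == "bh":
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    mean_a = np.expm1(a[:, tested]).mean(axis=0)
    mean_b = np.expm1(b[:, tested]).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    out = pd.DataFrame(
        {
            "avg_log2FC": log2fc,
            "p_value": p,
            "p_adj": p_adj,
            "pct_high": pct_a[tested],
            "pct_low": pct_b[tested],
        },
        index=x.gene_ids[tested],
    )
    out["passes"] = (out["avg_log2FC"] > min_log2fc) & (out["p_adj"] < alpha)
    return out.sort_values(["p_value", "avg_log2FC"], ascending=[True, False])


# ---------------------------------------------------------------------------
# composition tests
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a table given margins."""
    rs, cs = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(rs + 1).sum()
        + gammaln(cs + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _exact_2x3_pvalue(
    table: np.ndarray, seed: int, max_enum: int = 200_000, n_draws: int = 100_000
) -> float:
    """Exact independence test on a 2x3 table (Freeman-Halton).

    Full enumeration over tables with the observed margins when the
    candidate count is small, otherwise a seeded Monte Carlo estimate using
    margin-preserving random tables.
    """
    r1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)
    obs_logp = _log_table_prob(table)
    n_candidates = (min(r1, cols[0]) + 1) * (min(r1, cols[1]) + 1)
    if n_candidates <= max_enum:
        total = 0.0
        for a in range(min(r1, cols[0]) + 1):
            for b in range(min(r1, cols[1]) + 1):
                c = r1 - a - b
                if c < 0 or c > cols[2]:
                    continue
                cand = np.array(
                    [[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]]
                )
                lp = _log_table_prob(cand)
                if lp <= obs_logp + 1e-9:
                    total += math.exp(lp)
        return min(total, 1.0)
    rng = np.random.default_rng(seed)
    draws = random_table(table.sum(axis=1), cols).rvs(n_draws, random_state=rng)
    const = (
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(cols + 1).sum()
        - gammaln(table.sum() + 1)
    )
    lps = const - gammaln(draws + 1).sum(axis=(1, 2))
    return float((lps <= obs_logp + 1e-9).mean())


def composition_test(
    cell_types: pd.Series,
    states: pd.Series,
    alpha: float = 0.05,
    expected_min: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell-type 2x3 independence tests of state composition.

    For each cell type the table (this type vs all others) x (low /
    transition / high) is tested with chi-squared (df = 2); if any expected
    count falls below ``expected_min`` an exact test is used instead and the
    method recorded as ``fisher_exact``.  q-values are Benjamini-Hochberg
    across the tested cell types.
    """
    if len(cell_types) != len(states):
        raise ValueError("cell_types and states must align")
    ct = pd.Series(cell_types).astype(str)
    st = pd.Series(states).astype(str)
    if not set(st.unique()) <= set(STATES):
        raise ValueError(f"states must be in {STATES}")

    rows = []
    state_counts = st.value_counts()
    present_states = [s for s in STATES if state_counts.get(s, 0) > 0]
    if len(present_states) < 2:
        raise ValueError("need at least two non-empty states")
    for cell_type in sorted(ct.unique()):
        is_type = (ct == cell_type).to_numpy()
        table = np.array(
            [
                [(is_type & (st == s).to_numpy()).sum() for s in present_states],
                [(~is_type & (st == s).to_numpy()).sum() for s in present_states],
            ]
        )
        if (table.sum(axis=1) == 0).any():
            warnings.warn(
                f"cell type {cell_type!r}: empty margin, test skipped"
            )
            continue
        chi2, p_chi, dof, expected = chi2_contingency(table, correction=False)
        if (expected < expected_min).any() and table.shape[1] == 3:
            p = _exact_2x3_pvalue(table, seed=seed)
            method = "fisher_exact"
            stat = float("nan")
        elif (expected < expected_min).any():
            p = _exact_2x3_pvalue(
                np.column_stack([table, np.zeros(2, dtype=int)]), seed=seed
            )
            method = "fisher_exact"
            stat = float("nan")
        else:
            p, method, stat = p_chi, "chi_squared", chi2
        rows.append(
            {
                "cell_type": cell_type,
                "table": table,
                "statistic": stat,
                "p_value": p,
                "method": method,
            }
        )
    if not rows:
        raise ValueError("no testable cell type")
    out = pd.DataFrame(rows).set_index("cell_type")
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
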