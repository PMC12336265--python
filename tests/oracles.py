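"""Independent brute-force reference implementations used only by tests.

Each oracle is a direct, loop-based transcription of the statistic's
definition, kept deliberately separate from the vectorized package code.
"""

import math

import numpy as np
from scipy.stats import rankdata


def oracle_auc_recovery(values, in_set, top_frac=0.05):
    """Per-sample recovery-curve score by explicit curve enumeration."""
    n_genes = len(values)
    t = math.ceil(top_frac * n_genes)
    order = np.argsort(-np.asarray(values), kind="stable")
    n_set = int(np.sum(in_set))
    y_sum = 0
    hits = 0
    for k in range(1, t + 1):
        if in_set[order[k - 1]]:
            hits += 1
        y_sum += hits
    max_sum = sum(min(k, n_set) for k in range(1, t + 1))
    return y_sum / max_sum


def oracle_rank_u(values, in_set, r_max=1500):
    """Clipped Mann-Whitney score from first principles."""
    ranks = rankdata(-np.asarray(values))
    set_ranks = np.array([min(r, r_max + 1) for r, s in zip(ranks, in_set) if s])
    n_set = len(set_ranks)
    u = set_ranks.sum() - n_set * (n_set + 1) / 2
    return float(np.clip(1.0 - u / (n_set * r_max), 0.0, 1.0))


def oracle_sample_rank(values, in_set):
    """Rescaled mean rank from first principles."""
    ranks = rankdata(np.asarray(values))
    set_ranks = [r for r, s in zip(ranks, in_set) if s]
    n_set = len(set_ranks)
    n_genes = len(values)
    mr = float(np.mean(set_ranks))
    mr_min = (n_set + 1) / 2
    mr_max = n_genes - (n_set - 1) / 2
    return (mr - mr_min) / (mr_max - mr_min)


def oracle_weighted_ks(values, in_set, alpha=0.25):
    """Weighted KS running sum by explicit walk down the ranked list."""
    n_genes = len(values)
    order = np.argsort(-np.asarray(values), kind="stable")
    n_set = int(np.sum(in_set))
    w_total = 0.0
    for pos, g in enumerate(order, start=1):
        if in_set[g]:
            w_total += (n_genes - pos + 1) ** alpha
    p_in = 0.0
    p_out = 0.0
    total = 0.0
    for pos, g in enumerate(order, start=1):
        if in_set[g]:
            p_in += (n_genes - pos + 1) ** alpha / w_total
        else:
            p_out += 1.0 / (n_genes - n_set)
        total += p_in - p_out
    return total / n_genes


def oracle_binned_control(matrix, in_set, n_bins, n_ctrl, seed):
    """Module score replaying the same seeded control draw gene by gene."""
    vals = np.asarray(matrix, dtype=float)
    n_genes = vals.shape[1]
    mean = vals.mean(axis=0)
    order = np.argsort(mean, kind="stable")
    bin_id = np.empty(n_genes, dtype=int)
    for r, g in enumerate(order):
        bin_id[g] = min((r * n_bins) // n_genes, n_bins - 1)
    rng = np.random.default_rng(seed)
    set_idx = [g for g in range(n_genes) if in_set[g]]
    ctrl = []
    for g in set_idx:
        pool = [h for h in range(n_genes) if bin_id[h] == bin_id[g]]
        ctrl.extend(rng.choice(pool, size=n_ctrl, replace=True))
    return vals[:, set_idx].mean(axis=1) - vals[:, ctrl].mean(axis=1)


def oracle_auc(values, labels):
    """All-pairs concordance AUC (ties half-weighted)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases = values[labels]
    ctrls = values[~labels]
    total = 0.0
    for c in cases:
        for d in ctrls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(ctrls))


def oracle_quartile_counts(values):
    """Counts below q1 / above q3 via an explicit sort (type-7 quantiles)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def quant(q):
        h = (n - 1) * q
        lo = math.floor(h)
        return v[lo] + (h - lo) * (v[min(lo + 1, n - 1)] - v[lo])

    q1, q3 = quant(0.25), quant(0.75)
    return int(np.sum(v < q1)), int(np.sum(v > q3))
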