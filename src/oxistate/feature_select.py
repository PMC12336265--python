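"""Five-method feature-selection ensemble with strict intersection.

The candidate genes (typically DEGs intersected with co-expression module
genes and the bulk panel) are screened by five selectors on the labeled bulk
matrix:

``lasso``
    L1-penalized logistic regression over a log-spaced penalty grid with
    10-fold stratified CV; the penalty minimizing mean CV deviance is kept
    and genes with nonzero coefficients are selected.
``svm_rfe``
    Linear SVM recursive feature elimination dropping 10% of features per
    step; the surviving set at the feature count minimizing 5-fold CV error
    (ties -> fewer features) is selected.
``boruta``
    Shadow-feature selection: each iteration appends per-feature shuffled
    copies, fits a random forest, and scores a hit when a feature's
    importance exceeds the best shadow importance; features are confirmed or
    rejected by a two-sided binomial test at alpha = 0.01,
    Bonferroni-adjusted across features, over at most 40 iterations;
    undecided features are kept only if their hit record beats chance in the
    weaker unadjusted test.
``random_forest``
    A 500-tree forest; features with importance above the mean importance
    are selected.
``gbm``
    Depth-3 gradient boosting (learning rate 0.1, up to 100 rounds, round
    count chosen by 5-fold CV log-loss); features with relative influence
    above 1% are selected.

Hub genes are the exact five-way intersection, ordered by summed per-method
rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .containers import BulkStudy

__all__ = [
    "LabeledMatrix",
    "SelectionReport",
    "SELECTOR_METHODS",
    "prepare_design",
    "run_selector",
    "intersect_selections",
    "select_hub_genes",
]

SELECTOR_METHODS = ("lasso", "svm_rfe", "boruta", "random_forest", "gbm")


@dataclass
class LabeledMatrix:
    """Design matrix for the selectors: standardized + raw views, labels."""

    x_std: pd.DataFrame  # zero-mean / unit-variance per gene
    x_raw: pd.DataFrame
    y: np.ndarray  # 1 = case
    dropped_candidates: List[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.x_std.columns


@dataclass
class SelectionReport:
    """Per-method selections, rank tables, diagnostics, and the intersection."""

    selected: Dict[str, List[str]]
    ranks: Dict[str, pd.Series]  # per-method rank (1 = best)
    diagnostics: Dict[str, dict]
    intersection: List[str]
    seed: int


def prepare_design(bulk: BulkStudy, candidates: Sequence[str]) -> LabeledMatrix:
    """Restrict the bulk matrix to candidate genes and standardize.

    Candidates absent from the bulk panel are dropped (and recorded); the
    standardized view feeds the penalized and margin methods, the raw view
    the tree methods.
    """
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("candidate gene list is empty")
    present = [g for g in candidates if g in bulk.expr.columns]
    dropped = [g for g in candidates if g not in bulk.expr.columns]
    if dropped:
        warnings.warn(
            f"{len(dropped)} candidate gene(s) absent from the bulk panel"
        )
    if len(present) < 2:
        raise ValueError(
            f"only {len(present)} candidate genes survive restriction; need >= 2"
        )
    raw = bulk.expr[present]
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    std = (raw - mean) / sd
    return LabeledMatrix(
        x_std=std,
        x_raw=raw,
        y=bulk.is_case.astype(int),
        dropped_candidates=dropped,
    )


def _check_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    counts = np.bincount(y)
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 samples")


# ---------------------------------------------------------------------------
# individual selectors
# ---------------------------------------------------------------------------


def _select_lasso(m: LabeledMatrix, seed: int, rule: str = "min", n_penalties: int = 40):
    x = m.x_std.to_numpy()
    y = m.y
    cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
    cs = np.logspace(-2.5, 1.5, n_penalties)
    folds = list(cv.split(x, y))
    deviance = np.zeros((len(folds), len(cs)))
    for f, (tr, te) in enumerate(folds):
        for i, c in enumerate(cs):
            model = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", max_iter=2000,
                random_state=seed,
            )
            model.fit(x[tr], y[tr])
            proba = model.predict_proba(x[te])[:, 1]
            deviance[f, i] = 2.0 * log_loss(
                y[te], proba, labels=[0, 1], normalize=False
            )
    mean_dev = deviance.mean(axis=0)
    if rule == "min":
        c_idx = int(np.argmin(mean_dev))
    elif rule == "1se":
        se = deviance.std(axis=0, ddof=1) / np.sqrt(len(folds))
        best = int(np.argmin(mean_dev))
        ok = np.flatnonzero(mean_dev <= mean_dev[best] + se[best])
        c_idx = int(ok[0])  # strongest qualifying penalty
    else:
        raise ValueError(f"unknown lasso rule {rule!r}")
    final = LogisticRegression(
        l1_ratio=1.0, C=cs[c_idx], solver="liblinear", max_iter=2000,
        random_state=seed,
    ).fit(x, y)
    coef = final.coef_[0]
    selected_mask = coef != 0
    order = np.argsort(-np.abs(coef), kind="stable")
    ranks = pd.Series(
        np.empty(len(m.genes)), index=m.genes, dtype=float, name="lasso"
    )
    ranks.iloc[order] = np.arange(1, len(m.genes) + 1)
    diag = {
        "penalty_grid": cs.tolist(),
        "cv_deviance": mean_dev.tolist(),
        "chosen_C": float(cs[c_idx]),
        "n_selected": int(selected_mask.sum()),
    }
    return list(m.genes[selected_mask]), ranks, diag


def _select_svm_rfe(m: LabeledMatrix, seed: int, step: float = 0.1):
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    est = LinearSVC(C=1.0, dual=True, max_iter=20_000, random_state=seed)
    rfe = RFECV(est, step=step, cv=cv, scoring="accuracy", min_features_to_select=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rfe.fit(m.x_std.to_numpy(), m.y)
    ranks = pd.Series(rfe.ranking_.astype(float), index=m.genes, name="svm_rfe")
    diag = {
        "n_features_grid": [int(v) for v in rfe.cv_results_["n_features"]],
        "cv_error": [1 - float(v) for v in rfe.cv_results_["mean_test_score"]],
        "n_selected": int(rfe.n_features_),
    }
    return list(m.genes[rfe.support_]), ranks, diag


def _select_boruta(
    m: LabeledMatrix,
    seed: int,
    max_iter: int = 40,
    alpha: float = 0.01,
    n_trees: int = 500,
):
    """Shadow-feature selection with a fixed full-size shadow pool.

    Unlike implementations that shrink the shadow ensemble as features are
    decided, the shadow pool here always holds one shuffled copy of every
    original feature, so the "best chance importance" reference keeps the
    same null distribution at every iteration.  Decided real features do
    leave the design (for speed).  Confirm/reject decisions use the binomial
    test on the hit count, Bonferroni-adjusted across features; features that
    can no longer reach either decision stop early, and any still undecided
    at the end are kept only when their hit record clears the unadjusted
    one-sided binomial test at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    x = m.x_raw.to_numpy()
    n, p = x.shape
    active = np.ones(p, dtype=bool)  # undecided
    confirmed = np.zeros(p, dtype=bool)
    rejected = np.zeros(p, dtype=bool)
    hits = np.zeros(p, dtype=int)
    stuck = np.zeros(p, dtype=bool)
    trials = 0
    trials_seen = np.zeros(p, dtype=int)
    history = []
    imp_sum = np.zeros(p)
    shadow_max_history = []
    for it in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        shadows = x.copy()  # full pool, one shuffled copy per feature
        for j in range(p):
            rng.shuffle(shadows[:, j])
        design = np.hstack([x[:, idx], shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(design, m.y)
        imp = rf.feature_importances_
        real_imp, shadow_imp = imp[: idx.size], imp[idx.size:]
        imp_sum[idx] += real_imp
        trials_seen[idx] += 1
        shadow_max = float(shadow_imp.max())
        shadow_max_history.append(shadow_max)
        hits[idx] += (real_imp > shadow_max).astype(int)
        trials += 1
        # two-sided binomial decision, Bonferroni-adjusted over features
        h = hits[idx]
        thresh = alpha / 2 / p
        p_hi = binom.sf(h - 1, trials, 0.5)
        p_lo = binom.cdf(h, trials, 0.5)
        conf = p_hi < thresh
        rej = (p_lo < thresh) & ~conf
        confirmed[idx[conf]] = True
        rejected[idx[rej]] = True
        active[idx[conf | rej]] = False
        # futility: drop features that can no longer reach either decision
        # before max_iter; they end tentative and meet the rough fix below
        remaining = max_iter - trials
        if remaining > 0:
            idx2 = np.flatnonzero(active)
            h2 = hits[idx2]
            can_confirm = binom.sf(h2 + remaining - 1, max_iter, 0.5) < thresh
            can_reject = binom.cdf(h2, max_iter, 0.5) < thresh
            now_stuck = ~(can_confirm | can_reject)
            stuck[idx2[now_stuck]] = True
            active[idx2[now_stuck]] = False
        history.append(
            {
                "iteration": it + 1,
                "n_confirmed": int(confirmed.sum()),
                "n_rejected": int(rejected.sum()),
                "n_tentative": int(active.sum()),
            }
        )
    # tentative resolution: the weaker, unadjusted one-sided binomial test on
    # the hit record -- a feature must still beat the best shadow
    # significantly more often than chance to be kept
    tentative = np.flatnonzero(active | stuck)
    if tentative.size and trials:
        p_hi = binom.sf(
            hits[tentative] - 1, np.maximum(trials_seen[tentative], 1), 0.5
        )
        confirmed[tentative] = p_hi < alpha
    order = np.argsort(-hits, kind="stable")
    ranks = pd.Series(np.empty(p), index=m.genes, dtype=float, name="boruta")
    ranks.iloc[order] = np.arange(1, p + 1)
    diag = {
        "iterations": history,
        "hit_counts": {g: int(h) for g, h in zip(m.genes, hits)},
        "n_selected": int(confirmed.sum()),
    }
    return list(m.genes[confirmed]), ranks, diag


def _select_random_forest(
    m: LabeledMatrix, seed: int, n_trees: int = 500, importance: str = "impurity"
):
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(m.x_raw.to_numpy(), m.y)
    if importance == "impurity":
        imp = rf.feature_importances_
    elif importance == "permutation":
        from sklearn.inspection import permutation_importance

        imp = permutation_importance(
            rf, m.x_raw.to_numpy(), m.y, n_repeats=5, random_state=seed
        ).importances_mean
    else:
        raise ValueError(f"unknown importance {importance!r}")
    selected_mask = imp > imp.mean()
    order = np.argsort(-imp, kind="stable")
    ranks = pd.Series(np.empty(len(m.genes)), index=m.genes, dtype=float,
                      name="random_forest")
    ranks.iloc[order] = np.arange(1, len(m.genes) + 1)
    diag = {
        "importance": {g: float(v) for g, v in zip(m.genes, imp)},
        "threshold": float(imp.mean()),
        "n_selected": int(selected_mask.sum()),
    }
    return list(m.genes[selected_mask]), ranks, diag


def _select_gbm(
    m: LabeledMatrix,
    seed: int,
    max_rounds: int = 100,
    learning_rate: float = 0.1,
    influence_frac: float = 0.01,
):
    x = m.x_raw.to_numpy()
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    fold_loss = np.zeros((5, max_rounds))
    for f, (tr, te) in enumerate(cv.split(x, m.y)):
        model = GradientBoostingClassifier(
            max_depth=3,
            learning_rate=learning_rate,
            n_estimators=max_rounds,
            random_state=seed,
        )
        model.fit(x[tr], m.y[tr])
        for r, proba in enumerate(model.staged_predict_proba(x[te])):
            fold_loss[f, r] = log_loss(m.y[te], proba[:, 1], labels=[0, 1])
    mean_loss = fold_loss.mean(axis=0)
    best_rounds = int(np.argmin(mean_loss)) + 1
    model = GradientBoostingClassifier(
        max_depth=3,
        learning_rate=learning_rate,
        n_estimators=best_rounds,
        random_state=seed,
    )
    model.fit(x, m.y)
    influence = model.feature_importances_
    selected_mask = influence > influence_frac
    order = np.argsort(-influence, kind="stable")
    ranks = pd.Series(np.empty(len(m.genes)), index=m.genes, dtype=float, name="gbm")
    ranks.iloc[order] = np.arange(1, len(m.genes) + 1)
    diag = {
        "cv_logloss": mean_loss.tolist(),
        "best_rounds": best_rounds,
        "n_selected": int(selected_mask.sum()),
    }
    return list(m.genes[selected_mask]), ranks, diag


_SELECTORS = {
    "lasso": _select_lasso,
    "svm_rfe": _select_svm_rfe,
    "boruta": _select_boruta,
    "random_forest": _select_random_forest,
    "gbm": _select_gbm,
}


def run_selector(
    m: LabeledMatrix, method: str, seed: int = 0, **params
):
    """Run one named selector; returns (selected genes, rank series, diagnostics)."""
    if method not in _SELECTORS:
        raise ValueError(
            f"unknown method {method!r}; choose from {SELECTOR_METHODS}"
        )
    _check_classes(m.y)
    return _SELECTORS[method](m, seed=seed, **params)


def intersect_selections(
    selected: Dict[str, Sequence[str]], ranks: Optional[Dict[str, pd.Series]] = None
) -> List[str]:
    """Exact five-way intersection, ordered by summed per-method rank."""
    if len(selected) != 5:
        raise ValueError(f"need exactly five selections, got {len(selected)}")
    sets = [set(v) for v in selected.values()]
    common = set.intersection(*sets)
    if not common:
        return []
    if ranks:
        total = sum(r.loc[sorted(common)] for r in ranks.values())
        return list(total.sort_values(kind="stable").index)
    return sorted(common)


def select_hub_genes(
    bulk: BulkStudy,
    candidates: Sequence[str],
    methods: Sequence[str] = SELECTOR_METHODS,
    seed: int = 0,
    params: Optional[Dict[str, dict]] = None,
) -> SelectionReport:
    """Run the full ensemble and intersect: the hub-gene screen."""
    m = prepare_design(bulk, candidates)
    params = params or {}
    selected, ranks, diagnostics = {}, {}, {}
    for method in methods:
        sel, rk, diag = run_selector(m, method, seed=seed, **params.get(method, {}))
        selected[method], ranks[method], diagnostics[method] = sel, rk, diag
    intersection = (
        intersect_selections(selected, ranks) if len(selected) == 5 else []
    )
    return SelectionReport(
        selected=selected,
        ranks=ranks,
        diagnostics=diagnostics,
        intersection=intersection,
        seed=seed,
    )
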