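"""Variable selection: forest importance, L1-logistic, mRMR, pooling and RFE.

All selectors take a feature DataFrame (columns = feature names) and a
binary label vector, and return a subset of the input feature names —
never an invented id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .classifiers import ranking_importances
from .evaluation import auroc
from .io_config import child_seed


def rf_importance_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    rule: str = "above_mean",
    top_k: int = 50,
    cap: int = 200,
) -> list[str]:
    """Select features by impurity-based random-forest importance.

    ``above_mean`` keeps features with importance above the mean (capped
    at ``cap``); ``top_k`` keeps the ``top_k`` best.  Ordering is by
    importance descending, ties by name.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), np.asarray(y))
    imp = rf.feature_importances_
    order = sorted(range(X.shape[1]), key=lambda i: (-imp[i], X.columns[i]))
    if rule == "above_mean":
        chosen = [i for i in order if imp[i] > imp.mean()][:cap]
    elif rule == "top_k":
        chosen = order[: min(top_k, len(order))]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return [X.columns[i] for i in chosen]


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    cs: list[float] | None = None,
    cv: int = 5,
) -> list[str]:
    """L1-penalized logistic selection; penalty chosen by inner-CV AUROC.

    Features are standardized internally.  Among penalties whose mean
    out-of-fold AUROC is within one fold-level standard deviation of the
    best, the strongest penalty wins (a one-SD rule), so pure-noise inputs
    collapse to the empty or near-empty model.  Exact duplicates of an
    already-kept feature are dropped from the result — the solver may
    split weight across identical columns, but they carry no extra
    information.
    """
    cs = sorted(cs or [0.01, 0.1, 1.0, 10.0])  # ascending C = strongest penalty first
    y = np.asarray(y).astype(int) if np.asarray(y).dtype == bool else np.asarray(y)
    Xs = StandardScaler().fit_transform(X.to_numpy())
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))

    means, ses = [], []
    for c in cs:
        fold_scores = []
        for tr, te in splits:
            model = LogisticRegression(
                l1_ratio=1.0, C=c, solver="liblinear", random_state=seed, max_iter=2000
            ).fit(Xs[tr], y[tr])
            scores = model.predict_proba(Xs[te])[:, 1]
            fold_scores.append(auroc(y[te], scores))
        fold_scores = np.asarray(fold_scores)
        means.append(fold_scores.mean())
        ses.append(fold_scores.std(ddof=1))
    means = np.asarray(means)
    best = int(np.argmax(means))
    cutoff = means[best] - ses[best]
    chosen_c = cs[int(np.flatnonzero(means >= cutoff)[0])]

    final = LogisticRegression(
        l1_ratio=1.0, C=chosen_c, solver="liblinear", random_state=seed, max_iter=2000
    ).fit(Xs, y)
    coef = np.abs(final.coef_).ravel()
    idx = np.flatnonzero(coef > 1e-8)
    order = sorted(idx, key=lambda i: (-coef[i], X.columns[i]))
    kept: list[int] = []
    for i in order:
        dup = any(
            abs(np.corrcoef(Xs[:, i], Xs[:, j])[0, 1]) >= 1 - 1e-10 for j in kept
        )
        if not dup:
            kept.append(i)
    return [X.columns[i] for i in kept]


def mrmr_select(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance (F-statistic / correlation).

    Relevance is the class-wise ANOVA F statistic; redundancy is the mean
    absolute Pearson correlation with the already-selected set; the
    difference is maximized at each step.  Ties break by feature name.
    A candidate that exactly duplicates an already-selected feature
    (|corr| = 1) is skipped while any non-duplicate candidate remains —
    the F statistic's scale would otherwise drown the redundancy penalty.
    """
    if k > X.shape[1]:
        raise ValueError("k exceeds the number of features")
    y_arr = np.asarray(y)
    vals = X.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, _ = f_classif(vals, y_arr)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=0.0)

    sd = vals.std(axis=0)
    centered = vals - vals.mean(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    zs = centered / safe_sd

    names = list(X.columns)
    n = len(names)
    selected: list[int] = []
    redundancy_sum = np.zeros(n)
    max_corr = np.zeros(n)
    available = np.ones(n, dtype=bool)
    for _ in range(k):
        if selected:
            score = f_stat - redundancy_sum / len(selected)
        else:
            score = f_stat.copy()
        score[~available] = -np.inf
        is_dup = available & (max_corr >= 1 - 1e-10)
        if np.any(available & ~is_dup):
            score[is_dup] = -np.inf
        best = min(np.flatnonzero(score == score.max()), key=lambda i: names[i])
        selected.append(int(best))
        available[best] = False
        corr = np.abs(zs.T @ zs[:, best]) / len(y_arr)
        corr[sd == 0] = 0.0
        redundancy_sum += corr
        max_corr = np.maximum(max_corr, corr)
    return [names[i] for i in selected]


@dataclass
class FeaturePool:
    """Per-method selections and their deterministic, ordered union."""

    rf: list[str] = field(default_factory=list)
    lasso: list[str] = field(default_factory=list)
    mrmr: list[str] = field(default_factory=list)
    degs: list[str] = field(default_factory=list)
    clinical: list[str] = field(default_factory=list)
    pooled: list[str] = field(default_factory=list)


def pool_features(
    selections: dict[str, list[str]],
    degs: list[str],
    clinical: list[str],
) -> FeaturePool:
    """Union the method selections with the DEG list and clinical covariates.

    Order is deterministic: method priority (rf, lasso, mrmr, degs,
    clinical), names sorted within each method, first occurrence kept.
    Clinical features are always retained.
    """
    pool = FeaturePool(
        rf=list(selections.get("rf", [])),
        lasso=list(selections.get("lasso", [])),
        mrmr=list(selections.get("mrmr", [])),
        degs=list(degs),
        clinical=list(clinical),
    )
    seen: set[str] = set()
    pooled: list[str] = []
    for group in (pool.rf, pool.lasso, pool.mrmr, pool.degs, pool.clinical):
        for name in sorted(group):
            if name not in seen:
                seen.add(name)
                pooled.append(name)
    pool.pooled = pooled
    return pool


def rfe(
    X: pd.DataFrame,
    y: np.ndarray,
    pool: FeaturePool | list[str],
    estimator,
    target: int = 20,
    step_frac: float = 0.1,
    seed: int = 0,
    protected: list[str] | None = None,
) -> list[str]:
    """Recursive feature elimination down to ``target`` features.

    Each round drops the ``ceil(step_frac * current)`` lowest-ranked
    unprotected features (never overshooting the target).  Protected
    (clinical) features are exempt from elimination.  The result is
    ordered by the final fit's ranking, size exactly ``target``.
    """
    features = list(pool.pooled) if isinstance(pool, FeaturePool) else list(pool)
    protected_set = set(protected or [])
    if target > len(features):
        raise ValueError(f"target {target} exceeds pool size {len(features)}")

    def fit_importances(feats: list[str]) -> np.ndarray:
        est = clone(estimator)
        if hasattr(est, "random_state"):
            est.set_params(random_state=child_seed(seed, len(feats)))
        est.fit(X[feats].to_numpy(), np.asarray(y))
        return ranking_importances(est, len(feats))

    current = features
    while len(current) > target:
        imp = fit_importances(current)
        droppable = [
            (imp[i], current[i]) for i in range(len(current)) if current[i] not in protected_set
        ]
        n_drop = min(
            max(1, int(np.ceil(step_frac * len(current)))),
            len(current) - target,
            len(droppable),
        )
        if n_drop == 0:
            break
        drop = {name for _, name in sorted(droppable, key=lambda t: (t[0], t[1]))[:n_drop]}
        current = [f for f in current if f not in drop]

    imp = fit_importances(current)
    order = sorted(range(len(current)), key=lambda i: (-imp[i], current[i]))
    return [current[i] for i in order]
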