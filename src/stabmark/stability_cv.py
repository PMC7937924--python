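"""Repeated stratified K-fold cross-validation with per-fold selection,
tuning, training and the normalized stability score.

For each of the R*K fold plans, *using training data only*: recompute
DEGs, run the three selectors, pool, eliminate recursively to the target
panel, resample, tune by inner-CV AUROC, fit, then score the untouched
test fold.  Features surviving RFE are tallied; ``normalized_score`` is
the percentage of iterations in which a feature was selected.  Every
stochastic step is seeded from ``(seed, repeat, fold)``.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import dge, selection
from .classifiers import make_classifier, positive_class_scores
from .evaluation import confusion_metrics
from .imbalance import apply_sampler
from .io_config import OUTCOME_POSITIVE, ExpressionMatrix, RunConfig, child_seed


@dataclass
class FoldPlan:
    repeat: int  # 1..R
    fold: int  # 1..K
    train_ids: list[str]
    test_ids: list[str]


def make_fold_plans(
    labels: pd.Series, K: int = 5, R: int = 10, seed: int = 0
) -> list[FoldPlan]:
    """R repeats of a stratified K-fold partition, deterministic from seed.

    ``labels`` is indexed by sample id.  Within each repeat the test sets
    partition the cohort and class proportions per fold are within one
    sample of the stratified ideal.
    """
    ids = np.asarray(labels.index)
    y = np.asarray(labels.values).astype(str)
    plans: list[FoldPlan] = []
    for r in range(R):
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=child_seed(seed, r))
        for f, (tr, te) in enumerate(skf.split(ids, y)):
            plans.append(
                FoldPlan(
                    repeat=r + 1,
                    fold=f + 1,
                    train_ids=[str(s) for s in ids[tr]],
                    test_ids=[str(s) for s in ids[te]],
                )
            )
    return plans


def expand_grid(grid: dict[str, list]) -> list[dict]:
    """Exhaustive expansion preserving insertion order (the tie-break order)."""
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def tune_hyperparameters(
    X_train: np.ndarray,
    y_train: np.ndarray,
    classifier: str,
    grid: dict[str, list],
    inner_cv: int = 5,
    seed: int = 0,
) -> tuple[dict, list[dict]]:
    """Grid search scored by inner-CV mean AUROC; ties break by grid order."""
    from .evaluation import auroc

    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    candidates = expand_grid(grid)
    skf = StratifiedKFold(n_splits=inner_cv, shuffle=True, random_state=child_seed(seed, 97))
    splits = list(skf.split(X_train, y_train.astype(str)))

    results = []
    best_params, best_score = candidates[0], -np.inf
    for params in candidates:
        scores = []
        for tr, te in splits:
            clf = make_classifier(classifier, params, seed=child_seed(seed, 11))
            clf.fit(X_train[tr], y_train[tr])
            s = positive_class_scores(clf, X_train[te], _positive_label(y_train))
            scores.append(auroc(_as_bool(y_train[te]), s))
        mean_score = float(np.mean(scores))
        results.append({"params": params, "mean_auroc": mean_score})
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    return best_params, results


def _as_bool(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == bool:
        return y
    return y.astype(str) == OUTCOME_POSITIVE


def _positive_label(y: np.ndarray):
    y = np.asarray(y)
    if y.dtype == bool:
        return True
    return OUTCOME_POSITIVE


@dataclass
class FoldModel:
    """Everything fit_fold learned from one training fold."""

    plan: FoldPlan
    features: list[str]
    pool: selection.FeaturePool
    params: dict
    model: object
    sampler_counts: dict


@dataclass
class StabilityReport:
    scores: pd.DataFrame  # feature, times_selected, normalized_score
    n_iterations: int
    shortlist: list[str]
    threshold_pct: float


@dataclass
class CVReport:
    sampler: str
    classifier: str
    iterations: list[dict]
    summary: dict[str, dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sampler": self.sampler,
            "classifier": self.classifier,
            "summary": self.summary,
            "iterations": self.iterations,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")

    def to_table(self) -> pd.DataFrame:
        """One-row table shaped like a sampler-classifier performance listing."""
        row = {"sampler_classifier": f"{self.sampler}-{self.classifier}"}
        for metric in ("sensitivity", "specificity", "auroc", "mcc"):
            s = self.summary[metric]
            row[metric] = f"{s['mean']:.3f} ({s['lo']:.3f}-{s['hi']:.3f})"
        return pd.DataFrame([row])


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _feature_frame(
    mat: ExpressionMatrix, pheno: pd.DataFrame, clinical: list[str]
) -> pd.DataFrame:
    """Samples x (genes + available clinical covariates)."""
    X = mat.to_frame().T
    pheno_idx = pheno.set_index("sample_id").loc[X.index]
    for col in clinical:
        if col in pheno_idx.columns:
            X[col] = pheno_idx[col].astype(float).to_numpy()
    return X


def select_fold_features(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    mat_train: ExpressionMatrix,
    config: RunConfig,
    fold_seed: int,
    deg_list: list[str] | None = None,
) -> tuple[list[str], selection.FeaturePool]:
    """DEG recompute + three selectors + pooling + RFE, on training data only."""
    if deg_list is None:
        table = dge.dge_table(
            mat_train, y_train, fdr_cutoff=config.fdr_cutoff, lfc_cutoff=config.lfc_cutoff
        )
        deg_list = dge.select_degs(table, config.fdr_cutoff, config.lfc_cutoff).top_degs

    clinical = [c for c in config.clinical_features if c in X_train.columns]
    rf_list = selection.rf_importance_select(
        X_train, y_train, n_trees=config.rf_trees, seed=child_seed(fold_seed, 1)
    )
    lasso_list = selection.lasso_select(
        X_train, y_train, seed=child_seed(fold_seed, 2), cs=config.lasso_cs
    )
    mrmr_list = selection.mrmr_select(X_train, y_train, k=min(config.mrmr_k, X_train.shape[1]))
    pool = selection.pool_features(
        {"rf": rf_list, "lasso": lasso_list, "mrmr": mrmr_list},
        degs=deg_list,
        clinical=clinical,
    )
    if len(pool.pooled) <= config.rfe_target:
        return list(pool.pooled), pool
    est_params = (
        {"n_estimators": config.rfe_estimator_trees}
        if config.rfe_estimator in ("brf", "extra_trees")
        else {}
    )
    estimator = make_classifier(
        config.rfe_estimator, est_params, seed=child_seed(fold_seed, 3)
    )
    selected = selection.rfe(
        X_train,
        y_train,
        pool,
        estimator,
        target=config.rfe_target,
        step_frac=config.rfe_step_frac,
        seed=child_seed(fold_seed, 4),
        protected=clinical if config.protect_clinical else None,
    )
    return selected, pool


def fit_fold(
    mat: ExpressionMatrix,
    pheno: pd.DataFrame,
    plan: FoldPlan,
    config: RunConfig,
    deg_list: list[str] | None = None,
) -> FoldModel:
    """Train one fold end to end using only ``plan.train_ids``.

    Nothing from the test fold — values or labels — is touched here; the
    leakage guard in the test suite poisons test labels and asserts the
    fitted model is unchanged.
    """
    fold_seed = child_seed(config.seed, plan.repeat, plan.fold)
    pheno_idx = pheno.set_index("sample_id")
    y_train = (pheno_idx.loc[plan.train_ids, "outcome"] == OUTCOME_POSITIVE).to_numpy()
    if y_train.all() or not y_train.any():
        raise RuntimeError(
            f"repeat {plan.repeat} fold {plan.fold}: training partition has a single class"
        )
    mat_train = mat.subset_samples(plan.train_ids)
    X_train = _feature_frame(mat_train, pheno, config.clinical_features)

    features, pool = select_fold_features(
        X_train, y_train, mat_train, config, fold_seed, deg_list=deg_list
    )
    res = apply_sampler(
        config.sampler,
        X_train[features].to_numpy(),
        y_train,
        seed=child_seed(fold_seed, 5),
    )
    grid = config.grids.get(config.classifier, {})
    params, _ = tune_hyperparameters(
        res.X, res.y, config.classifier, grid,
        inner_cv=config.inner_cv, seed=child_seed(fold_seed, 6),
    )
    model = make_classifier(config.classifier, params, seed=child_seed(fold_seed, 7))
    model.fit(res.X, res.y)
    return FoldModel(
        plan=plan,
        features=features,
        pool=pool,
        params=params,
        model=model,
        sampler_counts={"before": res.counts_before, "after": res.counts_after},
    )


def summarize_stability(
    tallies: dict[str, int], R: int, K: int, threshold_pct: float = 60.0
) -> StabilityReport:
    """Normalized score = 100 * times_selected / (R*K); shortlist at threshold."""
    n_iter = R * K
    rows = [
        {
            "feature": feat,
            "times_selected": int(cnt),
            "normalized_score": 100.0 * cnt / n_iter,
        }
        for feat, cnt in tallies.items()
    ]
    scores = pd.DataFrame(rows, columns=["feature", "times_selected", "normalized_score"])
    if len(scores):
        scores = scores.sort_values(
            ["normalized_score", "feature"], ascending=[False, True]
        ).reset_index(drop=True)
    shortlist = scores.loc[
        (scores["normalized_score"] >= threshold_pct) & (scores["times_selected"] > 0),
        "feature",
    ].tolist()
    return StabilityReport(
        scores=scores, n_iterations=n_iter, shortlist=shortlist, threshold_pct=threshold_pct
    )


def _summary_stats(values: list[float | None]) -> dict:
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    valid = arr[~np.isnan(arr)]
    if len(valid) == 0:
        return {"mean": None, "lo": None, "hi": None}
    return {
        "mean": float(valid.mean()),
        "lo": float(np.percentile(valid, 2.5)),
        "hi": float(np.percentile(valid, 97.5)),
    }


def run_discovery(
    mat: ExpressionMatrix, pheno: pd.DataFrame, config: RunConfig
) -> tuple[CVReport, StabilityReport]:
    """The full discovery loop over R repeats of stratified K-fold CV."""
    labels = pheno.set_index("sample_id")["outcome"].loc[mat.sample_ids]
    plans = make_fold_plans(labels, K=config.n_folds, R=config.n_repeats, seed=config.seed)

    global_deg_list = None
    if config.global_degs:
        y_all = (labels == OUTCOME_POSITIVE).to_numpy()
        table = dge.dge_table(mat, y_all, config.fdr_cutoff, config.lfc_cutoff)
        global_deg_list = dge.select_degs(table, config.fdr_cutoff, config.lfc_cutoff).top_degs

    pheno_idx = pheno.set_index("sample_id")
    tallies: dict[str, int] = {}
    iterations: list[dict] = []
    X_all = _feature_frame(mat, pheno, config.clinical_features)
    for plan in plans:
        fm = fit_fold(mat, pheno, plan, config, deg_list=global_deg_list)
        for feat in fm.features:
            tallies[feat] = tallies.get(feat, 0) + 1
        y_test = (pheno_idx.loc[plan.test_ids, "outcome"] == OUTCOME_POSITIVE).to_numpy()
        scores = positive_class_scores(
            fm.model, X_all.loc[plan.test_ids, fm.features].to_numpy(), True
        )
        metrics = confusion_metrics(y_test, scores, config.threshold)
        iterations.append(
            {
                "repeat": plan.repeat,
                "fold": plan.fold,
                "params": fm.params,
                "n_selected": len(fm.features),
                "features": list(fm.features),
                "pool": {
                    "rf": list(fm.pool.rf),
                    "lasso": list(fm.pool.lasso),
                    "mrmr": list(fm.pool.mrmr),
                    "degs": list(fm.pool.degs),
                    "clinical": list(fm.pool.clinical),
                },
                "sampler_counts": fm.sampler_counts,
                "metrics": dataclasses.asdict(metrics),
            }
        )

    summary = {
        m: _summary_stats([it["metrics"][m] for it in iterations])
        for m in ("sensitivity", "specificity", "fpr", "mcc", "auroc")
    }
    cv_report = CVReport(
        sampler=config.sampler,
        classifier=config.classifier,
        iterations=iterations,
        summary=summary,
    )
    stability = summarize_stability(
        tallies, R=config.n_repeats, K=config.n_folds,
        threshold_pct=config.stability_threshold_pct,
    )
    return cv_report, stability
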