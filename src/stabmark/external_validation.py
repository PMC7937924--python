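"""Train-on-derivation / test-on-external-cohort protocol.

Cross-platform harmonization is per-gene z-scoring within each dataset
(config-disableable), so results are invariant to affine per-gene
rescaling of the validation matrix.  No validation sample ever reaches
selection, sampling, tuning or fitting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import selection
from .classifiers import make_classifier, positive_class_scores
from .evaluation import MetricSet, auroc, confusion_metrics, threshold_sweep
from .imbalance import apply_sampler
from .io_config import OUTCOME_NEGATIVE, OUTCOME_POSITIVE, ExpressionMatrix, RunConfig, child_seed
from .stability_cv import tune_hyperparameters


def align_features(
    derivation: ExpressionMatrix,
    validation: ExpressionMatrix,
    panel: list[str],
    min_shared_frac: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Intersect a feature panel with both datasets' gene sets.

    Errors when the shared fraction falls below ``min_shared_frac`` —
    a panel mostly absent from the validation platform cannot support a
    meaningful transfer.
    """
    der = set(derivation.gene_ids)
    val = set(validation.gene_ids)
    shared = [g for g in panel if g in der and g in val]
    dropped = [g for g in panel if g not in der or g not in val]
    if not shared:
        raise ValueError("no panel feature is present in both datasets")
    if len(shared) / len(panel) < min_shared_frac:
        raise ValueError(
            f"only {len(shared)}/{len(panel)} panel features shared; "
            f"below the {min_shared_frac:.0%} floor"
        )
    return shared, dropped


def severity_labels(scores: np.ndarray, cutoff: float, direction: str = "ge") -> np.ndarray:
    """Label samples complicated by severity-score cutoff (>= by default)."""
    scores = np.asarray(scores, dtype=float)
    if np.any(~np.isfinite(scores)):
        raise ValueError("severity scores contain missing values")
    if direction == "ge":
        pos = scores >= cutoff
    elif direction == "gt":
        pos = scores > cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return np.where(pos, OUTCOME_POSITIVE, OUTCOME_NEGATIVE)


def zscore_genes(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization (mean 0, SD 1; zero-variance genes left at 0)."""
    X = mat.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return ExpressionMatrix((X - mu) / sd, list(mat.gene_ids), list(mat.sample_ids))


@dataclass
class ValidationRun:
    derivation_id: str
    validation_id: str
    shared_features: list[str]
    dropped_features: list[str]
    sampler: str
    classifier: str
    selected_subset: list[str]
    params: dict
    auroc: float | None
    metrics: dict[str, MetricSet]  # "train_selected" and "post_hoc_best"

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")

    def to_table(self) -> pd.DataFrame:
        rows = []
        for label, m in self.metrics.items():
            rows.append(
                {
                    "dataset": self.validation_id,
                    "sampler_classifier": f"{self.sampler}-{self.classifier}",
                    "threshold_policy": label,
                    "threshold": m.threshold,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "auroc": self.auroc,
                    "mcc": m.mcc,
                }
            )
        return pd.DataFrame(rows)


def _panel_reselect(
    X: np.ndarray, y: np.ndarray, features: list[str], method: str, seed: int, top_k: int
) -> list[str]:
    frame = pd.DataFrame(X, columns=features)
    if method == "lasso":
        chosen = selection.lasso_select(frame, y, seed=seed)
        return chosen or features  # an empty lasso model falls back to the panel
    if method == "tree":
        return selection.rf_importance_select(
            frame, y, n_trees=250, seed=seed, rule="top_k", top_k=min(top_k, len(features))
        )
    raise ValueError(f"unknown reselect method {method!r}")


def run_validation(
    derivation: tuple[ExpressionMatrix, pd.DataFrame],
    validation: tuple[ExpressionMatrix, pd.DataFrame],
    panel: list[str],
    config: RunConfig,
    reselect: str = "lasso",
    derivation_id: str = "derivation",
    validation_id: str = "validation",
    standardize: bool = True,
    outcome_column: str = "outcome",
) -> ValidationRun:
    """Resample/select/tune/fit on the derivation cohort, score the external one.

    Reports metrics at a threshold chosen on derivation out-of-fold scores
    (honest protocol) and at the best achievable threshold on the
    validation scores (post-hoc, optimism-flagged), clearly labeled.
    """
    der_mat, der_pheno = derivation
    val_mat, val_pheno = validation
    shared, dropped = align_features(der_mat, val_mat, panel)

    if standardize:
        der_mat = zscore_genes(der_mat.subset_genes(shared))
        val_mat = zscore_genes(val_mat.subset_genes(shared))
    else:
        der_mat = der_mat.subset_genes(shared)
        val_mat = val_mat.subset_genes(shared)

    y_der = (
        der_pheno.set_index("sample_id").loc[der_mat.sample_ids, "outcome"]
        == OUTCOME_POSITIVE
    ).to_numpy()
    y_val = (
        val_pheno.set_index("sample_id").loc[val_mat.sample_ids, outcome_column]
    ).to_numpy()
    y_val = np.asarray(y_val).astype(str) == OUTCOME_POSITIVE

    seed = config.seed
    X_der = der_mat.values.T
    res = apply_sampler(config.sampler, X_der, y_der, seed=child_seed(seed, 21))
    subset = _panel_reselect(
        res.X, res.y, shared, reselect, seed=child_seed(seed, 22), top_k=config.rfe_target
    )
    cols = [shared.index(f) for f in subset]
    grid = config.grids.get(config.classifier, {})
    params, _ = tune_hyperparameters(
        res.X[:, cols], res.y, config.classifier, grid,
        inner_cv=config.inner_cv, seed=child_seed(seed, 23),
    )
    model = make_classifier(config.classifier, params, seed=child_seed(seed, 24))
    model.fit(res.X[:, cols], res.y)

    # honest threshold: chosen on derivation out-of-fold scores only
    skf = StratifiedKFold(config.inner_cv, shuffle=True, random_state=child_seed(seed, 25))
    oof = np.full(len(res.y), np.nan)
    for tr, te in skf.split(res.X[:, cols], res.y.astype(str)):
        m = make_classifier(config.classifier, params, seed=child_seed(seed, 26))
        m.fit(res.X[tr][:, cols], res.y[tr])
        oof[te] = positive_class_scores(m, res.X[te][:, cols], True)
    best_train, _ = threshold_sweep(res.y, oof, step=config.threshold_step)

    val_scores = positive_class_scores(model, val_mat.values.T[:, cols], True)
    try:
        val_auroc = auroc(y_val, val_scores)
    except ValueError:
        val_auroc = None
    train_metrics = confusion_metrics(y_val, val_scores, best_train.threshold)
    post_hoc_best, _ = threshold_sweep(y_val, val_scores, step=config.threshold_step)

    return ValidationRun(
        derivation_id=derivation_id,
        validation_id=validation_id,
        shared_features=shared,
        dropped_features=dropped,
        sampler=config.sampler,
        classifier=config.classifier,
        selected_subset=subset,
        params=params,
        auroc=val_auroc,
        metrics={"train_selected": train_metrics, "post_hoc_best": post_hoc_best},
    )
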