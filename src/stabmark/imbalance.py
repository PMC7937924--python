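"""Six resampling schemes for balancing training data.

All samplers operate on a feature matrix ``X`` and label vector ``y`` and
return a :class:`ResampleResult` with full provenance: per-row origin
tags, source indices for synthesized rows and the indices removed by
undersamplers.  Samplers are meant to be applied to training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import NearestNeighbors

from .classifiers import make_classifier

ORIGIN_ORIGINAL = "original"
ORIGIN_SYNTHETIC = "synthetic"
ORIGIN_CENTROID = "centroid"


@dataclass
class ResampleResult:
    X: np.ndarray
    y: np.ndarray
    origin: np.ndarray  # per-row tag
    removed: np.ndarray  # input indices dropped
    synthetic_sources: list[tuple[int, int]] = field(default_factory=list)
    counts_before: dict = field(default_factory=dict)
    counts_after: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)


def _label_counts(y: np.ndarray) -> dict:
    labels, counts = np.unique(y, return_counts=True)
    return {lab.item() if hasattr(lab, "item") else lab: int(c) for lab, c in zip(labels, counts)}


def _minority_majority(y: np.ndarray) -> tuple[object, object]:
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) != 2:
        raise ValueError(f"samplers require exactly 2 classes, got {len(labels)}")
    i = int(np.argmin(counts))
    return labels[i], labels[1 - i]


def _result(X, y, origin, removed, **kw) -> ResampleResult:
    return ResampleResult(
        X=np.asarray(X), y=np.asarray(y), origin=np.asarray(origin),
        removed=np.asarray(removed, dtype=int), counts_after=_label_counts(y), **kw
    )


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    seed: int = 0,
    open_interval: bool = True,
) -> ResampleResult:
    """Oversample the minority by interpolation toward k-NN minority neighbors.

    Each synthetic row is ``a + u * (b - a)`` for a random minority point
    ``a``, one of its ``k`` nearest minority neighbors ``b`` (Euclidean)
    and ``u ~ U(0, 1)`` (open interval by default, so synthetic rows never
    duplicate an original exactly).  Synthesis continues until
    minority/majority reaches ``target_ratio``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    minority, majority = _minority_majority(y)
    min_idx = np.flatnonzero(y == minority)
    maj_count = int(np.sum(y == majority))
    if len(min_idx) <= k:
        k = len(min_idx) - 1
        warnings.warn(f"minority count {len(min_idx)} <= k; lowering k to {k}")
    if k < 1:
        raise ValueError("need at least 2 minority samples for SMOTE")

    n_needed = int(np.ceil(target_ratio * maj_count)) - len(min_idx)
    counts_before = _label_counts(y)
    if n_needed <= 0:
        return _result(
            X.copy(), y.copy(), np.full(len(y), ORIGIN_ORIGINAL), [],
            counts_before=counts_before,
        )

    X_min = X[min_idx]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    new_rows = np.empty((n_needed, X.shape[1]))
    sources: list[tuple[int, int]] = []
    for i in range(n_needed):
        a = int(rng.integers(len(min_idx)))
        b = int(neighbors[a, rng.integers(k)])
        u = rng.random()
        while open_interval and u == 0.0:
            u = rng.random()
        new_rows[i] = X_min[a] + u * (X_min[b] - X_min[a])
        sources.append((int(min_idx[a]), int(min_idx[b])))

    X_out = np.vstack([X, new_rows])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    origin = np.concatenate(
        [np.full(len(y), ORIGIN_ORIGINAL), np.full(n_needed, ORIGIN_SYNTHETIC)]
    )
    return _result(
        X_out, y_out, origin, [], synthetic_sources=sources, counts_before=counts_before
    )


def random_undersample(X: np.ndarray, y: np.ndarray, seed: int = 0) -> ResampleResult:
    """Subsample the majority class without replacement to minority size."""
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    minority, majority = _minority_majority(y)
    maj_idx = np.flatnonzero(y == majority)
    m = int(np.sum(y == minority))
    keep_maj = np.sort(rng.choice(maj_idx, size=m, replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
    removed = np.setdiff1d(np.arange(len(y)), keep)
    return _result(
        X[keep], y[keep], np.full(len(keep), ORIGIN_ORIGINAL), removed,
        counts_before=_label_counts(y),
    )


def cluster_centroids(
    X: np.ndarray, y: np.ndarray, seed: int = 0, keep_nearest_instances: bool = False
) -> ResampleResult:
    """Replace the majority class by k-means centroids (k = minority count).

    With ``keep_nearest_instances`` the looser prose variant is used
    instead: keep the minority-count majority instances nearest to the
    single majority centroid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority, majority = _minority_majority(y)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    m = len(min_idx)
    counts_before = _label_counts(y)
    if len(maj_idx) <= m:
        return _result(
            X.copy(), y.copy(), np.full(len(y), ORIGIN_ORIGINAL), [],
            counts_before=counts_before,
        )

    if keep_nearest_instances:
        centroid = X[maj_idx].mean(axis=0)
        dist = np.linalg.norm(X[maj_idx] - centroid, axis=1)
        keep_maj = maj_idx[np.argsort(dist, kind="mergesort")[:m]]
        keep = np.sort(np.concatenate([min_idx, keep_maj]))
        removed = np.setdiff1d(np.arange(len(y)), keep)
        return _result(
            X[keep], y[keep], np.full(len(keep), ORIGIN_ORIGINAL), removed,
            counts_before=counts_before,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can trip ConvergenceWarning
        km = KMeans(n_clusters=m, random_state=seed, n_init=10).fit(X[maj_idx])
    X_out = np.vstack([X[min_idx], km.cluster_centers_])
    y_out = np.concatenate([y[min_idx], np.full(m, majority, dtype=y.dtype)])
    origin = np.concatenate([np.full(m, ORIGIN_ORIGINAL), np.full(m, ORIGIN_CENTROID)])
    return _result(X_out, y_out, origin, maj_idx, counts_before=counts_before)


def enn(
    X: np.ndarray, y: np.ndarray, k: int = 3, majority_only: bool = True
) -> ResampleResult:
    """Edited nearest neighbours: drop points whose k-NN vote disagrees.

    By default only majority-class points are eligible for removal (the
    goal is balancing); ``majority_only=False`` cleans both classes.
    Decisions use the original, unedited neighbourhood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) <= k:
        raise ValueError("need more samples than k")
    minority, majority = _minority_majority(y)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neigh = nn.kneighbors(X, return_distance=False)[:, 1:]  # excluding self
    same = (y[neigh] == y[:, None]).sum(axis=1)
    disagree = (k - same) > same  # strict majority vote against the label
    eligible = (y == majority) if majority_only else np.ones(len(y), dtype=bool)
    removed = np.flatnonzero(disagree & eligible)
    keep = np.setdiff1d(np.arange(len(y)), removed)
    return _result(
        X[keep], y[keep], np.full(len(keep), ORIGIN_ORIGINAL), removed,
        counts_before=_label_counts(y),
    )


def renn(
    X: np.ndarray, y: np.ndarray, k: int = 3, max_iter: int = 100,
    majority_only: bool = True,
) -> ResampleResult:
    """Repeatedly apply ENN until no further instance can be removed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts_before = _label_counts(y)
    keep = np.arange(len(y))
    n_iter = 0
    for _ in range(max_iter):
        res = enn(X[keep], y[keep], k=k, majority_only=majority_only)
        n_iter += 1
        if len(res.removed) == 0:
            break
        keep = np.delete(keep, res.removed)
        # stop if another pass could not possibly change anything
        if len(np.unique(y[keep])) < 2:
            break
    removed = np.setdiff1d(np.arange(len(y)), keep)
    return _result(
        X[keep], y[keep], np.full(len(keep), ORIGIN_ORIGINAL), removed,
        counts_before=counts_before, info={"n_iter": n_iter},
    )


def instance_hardness_threshold(
    X: np.ndarray, y: np.ndarray, estimator: str = "logit", cv: int = 5, seed: int = 0
) -> ResampleResult:
    """Drop the hardest majority instances until classes balance.

    Hardness is 1 minus the out-of-fold predicted probability of the true
    class under cross-validated fits of the named estimator.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority, majority = _minority_majority(y)
    clf = make_classifier(estimator, seed=seed)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    proba = cross_val_predict(clf, X, y, cv=skf, method="predict_proba", n_jobs=1)
    classes = np.unique(y)
    class_col = {c: i for i, c in enumerate(classes)}
    true_prob = proba[np.arange(len(y)), [class_col[c] for c in y]]
    hardness = 1.0 - true_prob

    maj_idx = np.flatnonzero(y == majority)
    n_remove = len(maj_idx) - int(np.sum(y == minority))
    order = maj_idx[np.argsort(-hardness[maj_idx], kind="mergesort")]
    removed = np.sort(order[:n_remove])
    keep = np.setdiff1d(np.arange(len(y)), removed)
    return _result(
        X[keep], y[keep], np.full(len(keep), ORIGIN_ORIGINAL), removed,
        counts_before=_label_counts(y), info={"hardness": hardness},
    )


SAMPLERS = {
    "smote": smote,
    "rus": random_undersample,
    "cluster_centroids": cluster_centroids,
    "enn": enn,
    "renn": renn,
    "iht": instance_hardness_threshold,
}


def apply_sampler(name: str, X: np.ndarray, y: np.ndarray, seed: int = 0) -> ResampleResult:
    """Apply a sampler by registry name with its default parameters."""
    if name in ("smote", "rus", "cluster_centroids", "iht"):
        return SAMPLERS[name](X, y, seed=seed)
    if name in ("enn", "renn"):
        return SAMPLERS[name](X, y)
    raise ValueError(f"unknown sampler {name!r}; known: {sorted(SAMPLERS)}")
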