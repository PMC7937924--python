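"""Classifier registry: anything with fit / predict_proba semantics qualifies.

Includes a from-scratch balanced random forest (each bootstrap sample is
randomly undersampled to class balance before tree growth — the per-tree
class counts are exposed so the contract can be asserted), an easy
ensemble (AdaBoost members on balanced undersamples) and a simple
probability-averaging stack.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier


class BalancedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Forest whose every bootstrap sample is undersampled to class balance.

    Each tree draws, with replacement, ``min_class_count`` samples from
    every class, then grows an ordinary decision tree on that balanced
    bootstrap.  Probabilities are averaged across trees.
    """

    def __init__(self, n_estimators=250, max_depth=None, max_features="sqrt", random_state=None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        class_idx = [np.flatnonzero(y_enc == c) for c in range(len(self.classes_))]
        m = min(len(idx) for idx in class_idx)
        self.estimators_ = []
        self.tree_class_counts_ = []
        for _ in range(self.n_estimators):
            boot = np.concatenate([rng.choice(idx, size=m, replace=True) for idx in class_idx])
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y_enc[boot])
            self.estimators_.append(tree)
            self.tree_class_counts_.append(np.bincount(y_enc[boot], minlength=len(self.classes_)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X)
        proba = np.zeros((X.shape[0], len(self.classes_)))
        for tree in self.estimators_:
            p = tree.predict_proba(X)
            proba[:, tree.classes_] += p
        return proba / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def feature_importances_(self):
        return np.mean([t.feature_importances_ for t in self.estimators_], axis=0)


class EasyEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost members, each trained on a random balanced undersample."""

    def __init__(self, n_estimators=10, adaboost_estimators=10, random_state=None):
        self.n_estimators = n_estimators
        self.adaboost_estimators = adaboost_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        class_idx = [np.flatnonzero(y_enc == c) for c in range(len(self.classes_))]
        m = min(len(idx) for idx in class_idx)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            sub = np.concatenate(
                [rng.choice(idx, size=m, replace=False) for idx in class_idx]
            )
            member = AdaBoostClassifier(
                n_estimators=self.adaboost_estimators,
                random_state=int(rng.integers(2**31 - 1)),
            )
            member.fit(X[sub], y_enc[sub])
            self.estimators_.append(member)
        return self

    def predict_proba(self, X):
        proba = np.zeros((np.asarray(X).shape[0], len(self.classes_)))
        for member in self.estimators_:
            proba += member.predict_proba(X)
        return proba / len(self.estimators_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class ProbabilityStack(BaseEstimator, ClassifierMixin):
    """Average the predicted probabilities of 2-3 member classifiers."""

    def __init__(self, members=None):
        self.members = members

    def fit(self, X, y):
        self.fitted_ = [clone(m).fit(X, y) for m in self.members]
        self.classes_ = self.fitted_[0].classes_
        return self

    def predict_proba(self, X):
        return np.mean([m.predict_proba(X) for m in self.fitted_], axis=0)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _make_logit(params, seed):
    lr_params = {"C": 1.0, "max_iter": 2000, **params}
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(random_state=seed, **lr_params)),
        ]
    )


_FACTORIES = {
    "brf": lambda params, seed: BalancedRandomForestClassifier(random_state=seed, **params),
    "extra_trees": lambda params, seed: ExtraTreesClassifier(
        n_estimators=250, random_state=seed, n_jobs=1, **params
    ),
    "logit": _make_logit,
    "gradient_boosting": lambda params, seed: GradientBoostingClassifier(
        random_state=seed, **params
    ),
    "xgboost": lambda params, seed: HistGradientBoostingClassifier(
        random_state=seed, **params
    ),
    "easy_ensemble": lambda params, seed: EasyEnsembleClassifier(random_state=seed, **params),
}

CLASSIFIER_NAMES = tuple(_FACTORIES)


def make_classifier(name: str, params: dict | None = None, seed: int = 0):
    """Build a classifier by registry name.

    ``stack:a+b`` builds a probability-averaging stack of members ``a``
    and ``b`` (each with default hyperparameters).
    """
    params = dict(params or {})
    if name.startswith("stack:"):
        member_names = name.split(":", 1)[1].split("+")
        if not 2 <= len(member_names) <= 3:
            raise ValueError("stacks take 2-3 members")
        members = [make_classifier(m, None, seed + i) for i, m in enumerate(member_names)]
        return ProbabilityStack(members=members)
    if name not in _FACTORIES:
        raise ValueError(f"unknown classifier {name!r}; known: {sorted(_FACTORIES)}")
    # ExtraTrees default differs from factory default when params given
    if name == "extra_trees":
        params.setdefault("n_estimators", 250)
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **params)
    return _FACTORIES[name](params, seed)


def positive_class_scores(estimator, X, positive_label=True) -> np.ndarray:
    """Column of predict_proba corresponding to the positive label."""
    proba = estimator.predict_proba(X)
    classes = list(estimator.classes_)
    return proba[:, classes.index(positive_label)]


def ranking_importances(estimator, n_features: int) -> np.ndarray:
    """Feature importances or |coef| for RFE-style ranking."""
    if hasattr(estimator, "feature_importances_"):
        return np.asarray(estimator.feature_importances_)
    if hasattr(estimator, "coef_"):
        return np.abs(np.asarray(estimator.coef_)).ravel()[:n_features]
    if hasattr(estimator, "named_steps"):
        last = list(estimator.named_steps.values())[-1]
        return ranking_importances(last, n_features)
    raise ValueError(f"no importances available on {type(estimator).__name__}")
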