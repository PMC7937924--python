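"""Metric battery, threshold sweeping and distributional validation.

Conventions: a score strictly greater than the threshold is a positive
call; AUROC is the Mann-Whitney rank statistic with ties credited 0.5;
any metric whose denominator is zero is reported as ``None`` and named in
the ``undefined`` marker rather than silently propagating NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class MetricSet:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float
    sensitivity: float | None = None
    specificity: float | None = None
    fpr: float | None = None
    mcc: float | None = None
    auroc: float | None = None
    undefined: tuple[str, ...] = field(default_factory=tuple)


def metrics_from_counts(
    tp: int, tn: int, fp: int, fn: int, threshold: float = 0.5, auroc: float | None = None
) -> MetricSet:
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    fpr = ratio(fp, fp + tn, "fpr")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(
        tp=tp, tn=tn, fp=fp, fn=fn, threshold=threshold,
        sensitivity=sens, specificity=spec, fpr=fpr, mcc=mcc, auroc=auroc,
        undefined=tuple(undefined),
    )


def _binary(y_true: np.ndarray) -> np.ndarray:
    y = np.asarray(y_true)
    if y.dtype == bool:
        return y
    if y.dtype.kind in "iuf":
        return y.astype(bool)
    from .io_config import OUTCOME_POSITIVE

    return y.astype(str) == OUTCOME_POSITIVE


def auroc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Mann-Whitney AUROC; tied scores credit 0.5 per pair."""
    y = _binary(y_true)
    s = np.asarray(y_score, dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def confusion_metrics(y_true: np.ndarray, y_score: np.ndarray, threshold: float) -> MetricSet:
    """Counts and derived metrics at a threshold (score > threshold = positive)."""
    y = _binary(y_true)
    s = np.asarray(y_score, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    pred = s > threshold
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    try:
        auc = auroc(y, s)
    except ValueError:
        auc = None
    return metrics_from_counts(tp, tn, fp, fn, threshold=threshold, auroc=auc)


def threshold_sweep(
    y_true: np.ndarray,
    y_score: np.ndarray,
    step: float = 0.001,
    criterion: str = "max_mcc",
) -> tuple[MetricSet, pd.DataFrame]:
    """Evaluate thresholds {0, step, ..., 1}; pick the best by criterion.

    Ties go to the lowest threshold.  Returns the winning MetricSet and
    the full sweep table (one row per threshold).
    """
    if criterion not in ("max_mcc", "max_youden"):
        raise ValueError(f"unknown criterion {criterion!r}")
    y = _binary(y_true)
    s = np.asarray(y_score, dtype=float)
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 into an integer number of steps")
    thresholds = np.linspace(0.0, 1.0, n_steps + 1)

    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    n1, n0 = len(pos_sorted), len(neg_sorted)
    tp = n1 - np.searchsorted(pos_sorted, thresholds, side="right")
    fp = n0 - np.searchsorted(neg_sorted, thresholds, side="right")
    fn = n1 - tp
    tn = n0 - fp

    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(n1 > 0, tp / max(n1, 1), np.nan)
        spec = np.where(n0 > 0, tn / max(n0, 1), np.nan)
        fpr = np.where(n0 > 0, fp / max(n0, 1), np.nan)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.maximum(denom, 1)), np.nan)

    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "sensitivity": sens, "specificity": spec, "fpr": fpr, "mcc": mcc,
        }
    )
    score = mcc if criterion == "max_mcc" else sens + spec - 1.0
    score = np.where(np.isnan(score), -np.inf, score)
    best_idx = int(np.flatnonzero(score == score.max())[0])
    best = metrics_from_counts(
        int(tp[best_idx]), int(tn[best_idx]), int(fp[best_idx]), int(fn[best_idx]),
        threshold=float(thresholds[best_idx]),
    )
    try:
        best.auroc = auroc(y, s)
    except ValueError:
        pass
    return best, table


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    bootstrap_mean: float | None = None
    n_boot: int | None = None
    seed: int | None = None


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    xs, ys = np.sort(x), np.sort(y)
    pts = np.concatenate([xs, ys])
    cdf1 = np.searchsorted(xs, pts, side="right") / len(xs)
    cdf2 = np.searchsorted(ys, pts, side="right") / len(ys)
    return float(np.abs(cdf1 - cdf2).max())


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> KSResult:
    """Two-sample KS: sup-norm ECDF difference with asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    d = _ks_d(x, y)
    ne = len(x) * len(y) / (len(x) + len(y))
    p = float(np.clip(special.kolmogorov(math.sqrt(ne) * d), 0.0, 1.0))
    return KSResult(statistic=d, p_value=p, n1=len(x), n2=len(y))


def ks_bootstrap(x: np.ndarray, y: np.ndarray, n_boot: int = 1000, seed: int = 0) -> KSResult:
    """Bootstrap/permutation KS for small samples.

    ``bootstrap_mean`` is the mean D over resamples drawn with replacement
    at the original sizes; the p-value is the fraction of label-permuted
    resamples with D at least the observed value.  Because D is heavily
    discrete at small n, a mid-p correction (ties between permuted and
    observed D count half) keeps the null p-value approximately calibrated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    d_obs = _ks_d(x, y)
    n1, n2 = len(x), len(y)

    boot_ds = np.empty(n_boot)
    for i in range(n_boot):
        boot_ds[i] = _ks_d(
            rng.choice(x, size=n1, replace=True), rng.choice(y, size=n2, replace=True)
        )
    pooled = np.concatenate([x, y])
    greater = ties = 0
    for _ in range(n_boot):
        perm = rng.permutation(pooled)
        d = _ks_d(perm[:n1], perm[n1:])
        if d > d_obs + 1e-12:
            greater += 1
        elif abs(d - d_obs) <= 1e-12:
            ties += 1
    p = (greater + 0.5 * ties + 0.5) / (n_boot + 1)
    return KSResult(
        statistic=d_obs, p_value=p, n1=n1, n2=n2,
        bootstrap_mean=float(boot_ds.mean()), n_boot=n_boot, seed=seed,
    )


def kde_summary(values: np.ndarray, grid_size: int = 256) -> pd.DataFrame:
    """Gaussian KDE (Scott's rule) on an even grid spanning data +/- 3 bandwidths."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2 or np.ptp(values) == 0:
        raise ValueError("KDE requires non-constant input (zero bandwidth)")
    kde = stats.gaussian_kde(values)
    bw = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, grid_size)
    return pd.DataFrame({"x": grid, "density": kde(grid)})


def ks_feature_table(
    features: pd.DataFrame, y_true: np.ndarray, bootstrap_below_n: int = 0,
    n_boot: int = 1000, seed: int = 0,
) -> pd.DataFrame:
    """Per-feature two-sample KS between classes (bootstrap variant for small n)."""
    y = _binary(y_true)
    rows = []
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        x1, x0 = v[y], v[~y]
        if min(len(x1), len(x0)) < bootstrap_below_n:
            res = ks_bootstrap(x1, x0, n_boot=n_boot, seed=seed)
        else:
            res = ks_two_sample(x1, x0)
        rows.append({"feature": name, "statistic": res.statistic, "p_value": res.p_value})
    return pd.DataFrame(rows).sort_values("statistic", ascending=False).reset_index(drop=True)
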