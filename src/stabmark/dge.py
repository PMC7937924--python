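"""Moderated-t differential expression with BH-FDR control and fold-change filters.

The two-group moderated t shrinks per-gene residual variances toward a
common prior fitted by moment matching on the log sample variances
(trigamma-free approximation), then tests ``log2fc / (s_tilde *
sqrt(1/n1 + 1/n0))`` against a t distribution with ``d0 + d`` degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_config import OUTCOME_POSITIVE, ExpressionMatrix

D0_CAP = 1e6

DGE_COLUMNS = [
    "gene_id",
    "log2fc",
    "avg_expr",
    "t_mod",
    "df_total",
    "p",
    "p_adj",
    "is_deg",
    "is_top_deg",
    "category",
    "zero_variance",
]


def _as_positive_mask(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    if labels.dtype.kind in "iu" and set(np.unique(labels)) <= {0, 1}:
        return labels.astype(bool)
    return labels.astype(str) == OUTCOME_POSITIVE


def fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match prior df ``d0`` and scale ``s0^2`` from log sample variances.

    Uses ``E[log s^2] = log s0^2 + psi(d/2) - log(d/2)`` and
    ``Var[log s^2] = psi'(d/2) + psi'(d0/2)``, with the large-argument
    approximation ``psi'(d0/2) ~ 2/d0`` for the inversion.
    """
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return D0_CAP, float(s2.mean()) if len(s2) else 1.0
    e = np.log(s2) - special.digamma(d / 2) + np.log(d / 2)
    excess = e.var(ddof=1) - special.polygamma(1, d / 2)
    d0 = D0_CAP if excess <= 2.0 / D0_CAP else min(2.0 / excess, D0_CAP)
    log_s0sq = e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)
    return float(d0), float(np.exp(log_s0sq))


def moderated_t_test(
    mat: ExpressionMatrix,
    labels: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene two-group moderated t-test (positive minus negative class).

    ``prior_df`` overrides the estimated prior degrees of freedom; 0
    disables moderation, recovering the ordinary pooled two-sample t.
    Genes with zero variance in both classes get ``t_mod = 0, p = 1``
    and a ``zero_variance`` flag.
    """
    pos = _as_positive_mask(labels)
    if len(pos) != mat.n_samples:
        raise ValueError("labels must match sample count")
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >=2 samples per class, got {n1}/{n0}")

    X1, X0 = mat.values[:, pos], mat.values[:, ~pos]
    mean1, mean0 = X1.mean(axis=1), X0.mean(axis=1)
    log2fc = mean1 - mean0
    avg_expr = mat.values.mean(axis=1)
    d = n1 + n0 - 2
    ss = ((X1 - mean1[:, None]) ** 2).sum(axis=1) + ((X0 - mean0[:, None]) ** 2).sum(axis=1)
    s2 = ss / d
    zero_var = s2 <= 0

    if prior_df is None:
        d0, s0sq = fit_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0sq = fit_variance_prior(s2, d)[1] if d0 > 0 else 1.0

    s2_post = (d0 * s0sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    df_total = min(d0 + d, D0_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    t_mod[zero_var] = 0.0
    p[zero_var] = 1.0

    return pd.DataFrame(
        {
            "gene_id": mat.gene_ids,
            "log2fc": log2fc,
            "avg_expr": avg_expr,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "zero_variance": zero_var,
        }
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def dge_table(
    mat: ExpressionMatrix,
    labels: np.ndarray,
    fdr_cutoff: float = 0.1,
    lfc_cutoff: float = 1.0,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full differential-expression table with BH adjustment and DEG flags."""
    table = moderated_t_test(mat, labels, prior_df=prior_df)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["is_deg"] = table["p_adj"] < fdr_cutoff
    table["is_top_deg"] = table["is_deg"] & (table["log2fc"].abs() >= lfc_cutoff)
    table["category"] = np.where(
        table["is_top_deg"], "lfc+sig", np.where(table["is_deg"], "sig-only", "ns")
    )
    return table[DGE_COLUMNS]


@dataclass
class DEGLists:
    all_degs: list[str]
    top_degs: list[str]
    up: list[str]
    down: list[str]


def select_degs(
    table: pd.DataFrame, fdr_cutoff: float = 0.1, lfc_cutoff: float = 1.0
) -> DEGLists:
    """Partition DEGs, ordered by (p, |log2fc| descending, gene id)."""
    t = table.copy()
    t["_abs_lfc"] = t["log2fc"].abs()
    t = t.sort_values(["p", "_abs_lfc", "gene_id"], ascending=[True, False, True])
    deg = t[t["p_adj"] < fdr_cutoff]
    top = deg[deg["_abs_lfc"] >= lfc_cutoff]
    return DEGLists(
        all_degs=deg["gene_id"].tolist(),
        top_degs=top["gene_id"].tolist(),
        up=deg.loc[deg["log2fc"] > 0, "gene_id"].tolist(),
        down=deg.loc[deg["log2fc"] < 0, "gene_id"].tolist(),
    )


def write_dge_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
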