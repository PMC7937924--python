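"""Synthetic cohorts with planted differential expression.

The generator produces log2-scale expression matrices whose structure
mirrors a pediatric septic-shock derivation cohort: a minority
"complicated" class, a small set of genes with strong planted effects, a
larger set with weak effects, additive per-gene batch shifts, a severity
score correlated with outcome and mortality nested inside the positive
class.  Every draw is reproducible from the spec's seed.

Per gene ``g`` and sample ``i``::

    x[g, i] = b[g] + gamma[batch(i), g] + delta[g] * 1[outcome(i) == complicated] + eps[g, i]

with ``b[g] ~ N(7, 1.5)``, ``gamma[b, g] ~ N(0, batch_shift_sd)``,
``eps[g, i] ~ N(0, sigma[g]^2)`` and ``sigma[g] ~ U[sigma_lo, sigma_hi]``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_config import OUTCOME_NEGATIVE, OUTCOME_POSITIVE, ExpressionMatrix

STRONG_DELTA_RANGE = (2.0, 3.0)
WEAK_DELTA_RANGE = (0.2, 1.0)


@dataclass
class SyntheticSpec:
    """Parameters of the planted-effect generative model."""

    n_samples: int = 228
    prevalence: float = 52 / 228
    n_genes: int = 2000
    n_strong: int = 17
    n_weak: int = 50
    frac_up: float = 808 / 1269
    sigma_lo: float = 0.3
    sigma_hi: float = 0.8
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    severity_effect: float = 1.2
    mortality_rate_in_positive: float = 28 / 52
    exact_prevalence: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_strong + self.n_weak > self.n_genes:
            raise ValueError("n_strong + n_weak must not exceed n_genes")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    strong_genes: list[str]
    weak_genes: list[str]
    deltas: dict[str, float]
    batch_shifts: dict[str, list[float]]  # gene -> per-batch additive shift
    spec: SyntheticSpec

    @property
    def planted_genes(self) -> list[str]:
        return self.strong_genes + self.weak_genes

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["spec"] = dataclasses.asdict(self.spec)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _draw_truth(spec: SyntheticSpec, rng: np.random.Generator) -> GroundTruth:
    genes = _gene_ids(spec.n_genes)
    planted_idx = rng.choice(spec.n_genes, size=spec.n_strong + spec.n_weak, replace=False)
    strong_idx = planted_idx[: spec.n_strong]
    weak_idx = planted_idx[spec.n_strong :]

    deltas: dict[str, float] = {}
    for idx_set, (lo, hi) in ((strong_idx, STRONG_DELTA_RANGE), (weak_idx, WEAK_DELTA_RANGE)):
        for i in idx_set:
            magnitude = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < spec.frac_up else -1.0
            deltas[genes[i]] = sign * magnitude

    shifts = rng.normal(0.0, spec.batch_shift_sd, size=(spec.n_batches, spec.n_genes))
    if spec.n_batches == 1:
        shifts[:] = 0.0
    batch_shifts = {genes[g]: [float(v) for v in shifts[:, g]] for g in range(spec.n_genes)}
    return GroundTruth(
        strong_genes=[genes[i] for i in strong_idx],
        weak_genes=[genes[i] for i in weak_idx],
        deltas=deltas,
        batch_shifts=batch_shifts,
        spec=spec,
    )


def _sample_cohort(
    spec: SyntheticSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
    sample_prefix: str,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    n = spec.n_samples
    genes = _gene_ids(spec.n_genes)

    if spec.exact_prevalence:
        n_pos = int(round(n * spec.prevalence))
        is_pos = np.zeros(n, dtype=bool)
        is_pos[rng.choice(n, size=n_pos, replace=False)] = True
    else:
        is_pos = rng.random(n) < spec.prevalence

    min_per_fold = int(is_pos.sum()) // 5
    if min_per_fold < 2:
        warnings.warn(
            f"only {int(is_pos.sum())} positives: fewer than 2 per fold at 5-fold CV"
        )

    batch = rng.integers(0, spec.n_batches, size=n)
    baseline = rng.normal(7.0, 1.5, size=spec.n_genes)
    sigma = rng.uniform(spec.sigma_lo, spec.sigma_hi, size=spec.n_genes)

    delta_vec = np.array([truth.deltas.get(g, 0.0) for g in genes])
    shift_mat = np.array([truth.batch_shifts[g] for g in genes])  # genes x batches

    eps = rng.normal(0.0, 1.0, size=(spec.n_genes, n)) * sigma[:, None]
    values = (
        baseline[:, None]
        + shift_mat[:, batch]
        + delta_vec[:, None] * is_pos[None, :]
        + eps
    )

    severity = rng.normal(0.0, 1.0, size=n) + spec.severity_effect * is_pos
    mortality = np.zeros(n, dtype=bool)
    pos_idx = np.flatnonzero(is_pos)
    mortality[pos_idx] = rng.random(len(pos_idx)) < spec.mortality_rate_in_positive

    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(1, n + 1)]
    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "outcome": np.where(is_pos, OUTCOME_POSITIVE, OUTCOME_NEGATIVE),
            "batch": [f"batch{b + 1}" for b in batch],
            "severity_score": severity,
            "mortality": mortality,
            "age": rng.uniform(0.1, 12.0, size=n),
            "sex": rng.choice(["male", "female"], size=n),
        }
    )
    mat = ExpressionMatrix(values, genes, sample_ids)
    return mat, pheno


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a derivation cohort with planted effects.

    Returns the expression matrix, the phenotype table and the ground
    truth (planted gene ids, their effect sizes and per-batch shifts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    truth = _draw_truth(spec, rng)
    mat, pheno = _sample_cohort(spec, truth, rng, sample_prefix="S")
    return mat, pheno, truth


def generate_validation_cohort(
    spec: SyntheticSpec,
    truth: GroundTruth,
    attenuation: float,
    retained_fraction: float,
    seed: int,
    label_name: str = "outcome",
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate an external cohort sharing the derivation's planted genes.

    Only ``ceil(retained_fraction * n)`` of the planted genes (strong and
    weak counted separately) keep their effect, each scaled by
    ``attenuation``; the rest become null.  Sample ids are distinct from
    the derivation cohort; ``label_name`` optionally renames the outcome
    column (e.g. to ``mortality``).
    """
    if not 0 <= attenuation <= 1:
        raise ValueError("attenuation must be in [0, 1]")
    if not 0 <= retained_fraction <= 1:
        raise ValueError("retained_fraction must be in [0, 1]")

    def retained(ids: list[str]) -> set[str]:
        k = int(np.ceil(retained_fraction * len(ids)))
        return set(ids[:k])

    keep = retained(truth.strong_genes) | retained(truth.weak_genes)
    deltas = {
        g: (attenuation * d if g in keep else 0.0) for g, d in truth.deltas.items()
    }
    val_truth = GroundTruth(
        strong_genes=[g for g in truth.strong_genes if g in keep and deltas[g] != 0.0],
        weak_genes=[g for g in truth.weak_genes if g in keep and deltas[g] != 0.0],
        deltas=deltas,
        batch_shifts=truth.batch_shifts,
        spec=spec,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    mat, pheno = _sample_cohort(spec, val_truth, rng, sample_prefix="V")
    if label_name != "outcome":
        pheno = pheno.rename(columns={"outcome": label_name})
    return mat, pheno, val_truth
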