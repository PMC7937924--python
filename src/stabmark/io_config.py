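"""Readers/writers, run configuration and cohort summaries.

The pipeline exchanges four plain-text formats:

* expression matrices — TSV, genes as rows (first column = gene id),
  samples as columns (header row), or the value block of the GEO
  series-matrix text dialect;
* phenotype tables — CSV with one row per sample;
* run configuration — JSON;
* reports — JSON and TSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

OUTCOME_POSITIVE = "complicated"
OUTCOME_NEGATIVE = "uncomplicated"

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values.

    Invariants (checked on construction): shape matches the identifier
    lists, identifiers are unique within their axis and every value is
    finite.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for axis_name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {axis_name} ids: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(sample_ids))

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return ExpressionMatrix(self.values[idx, :], list(gene_ids), list(self.sample_ids))


def _duplicates(ids: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``series_matrix`` text.

    Duplicate gene ids are rejected — collapsing probe-level rows to gene
    symbols is an explicit, separate step (:func:`stabmark.preprocess.collapse_probes`).
    """
    path = Path(path)
    if format == "tsv":
        lines = path.read_text().splitlines()
        return _parse_matrix_lines(lines, first_line_no=1, sep="\t", source=str(path))
    if format == "series_matrix":
        lines = path.read_text().splitlines()
        try:
            begin = next(i for i, l in enumerate(lines) if l.strip() == SERIES_MATRIX_BEGIN)
            end = next(i for i, l in enumerate(lines) if l.strip() == SERIES_MATRIX_END)
        except StopIteration:
            raise ParseError(f"{path}: missing series-matrix table sentinels") from None
        block = lines[begin + 1 : end]
        block = [l.replace('"', "") for l in block]
        return _parse_matrix_lines(block, first_line_no=begin + 2, sep="\t", source=str(path))
    raise ValueError(f"unknown expression format: {format!r}")


def _parse_matrix_lines(
    lines: list[str], first_line_no: int, sep: str, source: str
) -> ExpressionMatrix:
    rows = [l for l in lines if l.strip()]
    if not rows:
        raise ParseError(f"{source}: empty matrix")
    header = rows[0].rstrip("\n").split(sep)
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{source}:{first_line_no}: malformed header (no sample columns)")
    dupes = _duplicates(sample_ids)
    if dupes:
        raise ParseError(
            f"{source}:{first_line_no}: duplicate sample id {sorted(dupes)[0]!r}"
        )
    gene_ids: list[str] = []
    values: list[list[float]] = []
    for offset, line in enumerate(rows[1:], start=1):
        line_no = first_line_no + offset
        parts = line.rstrip("\n").split(sep)
        if len(parts) != len(sample_ids) + 1:
            raise ParseError(
                f"{source}:{line_no}: expected {len(sample_ids) + 1} fields, got {len(parts)}"
            )
        gene_ids.append(parts[0])
        try:
            values.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{source}:{line_no}: non-numeric cell ({exc})") from None
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ParseError(f"{source}: duplicate gene id {sorted(dupes)[0]!r}")
    return ExpressionMatrix(np.array(values, dtype=float), gene_ids, sample_ids)


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV readable back by :func:`read_expression` (6-decimal values)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(mat.sample_ids) + "\n")
        for gene, row in zip(mat.gene_ids, mat.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

PHENOTYPE_REQUIRED = ("sample_id", "outcome")
PHENOTYPE_OPTIONAL = ("batch", "severity_score", "mortality", "age", "sex", "pathogen")


def validate_phenotype(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table (one row per sample) and return it."""
    for col in PHENOTYPE_REQUIRED:
        if col not in pheno.columns:
            raise ValueError(f"phenotype table missing required column {col!r}")
    if pheno["sample_id"].duplicated().any():
        dup = pheno.loc[pheno["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in phenotype table")
    bad = set(pheno["outcome"].dropna()) - {OUTCOME_POSITIVE, OUTCOME_NEGATIVE}
    if bad:
        raise ValueError(f"unknown outcome labels: {sorted(bad)}")
    return pheno


def read_phenotype(path: str | Path) -> pd.DataFrame:
    return validate_phenotype(pd.read_csv(path))


def write_phenotype(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with halves going away from zero (61.5 -> 62, -61.5 -> -62)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    if total == 0:
        raise ZeroDivisionError("percentage of an empty group")
    return round_half_away(100.0 * count / total, decimals)


@dataclass
class CohortSummary:
    n_total: int
    n_by_outcome: dict[str, int]
    pct_by_outcome: dict[str, float]
    pct_male: float | None
    pct_male_by_outcome: dict[str, float]
    pct_mortality_in_positive: float | None
    pathogen_counts: dict[str, int]
    pathogen_pct: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def summarize_cohort(
    pheno: pd.DataFrame,
    decimals: int = 1,
    field_decimals: dict[str, int] | None = None,
) -> CohortSummary:
    """Counts and percentages describing a cohort.

    ``field_decimals`` overrides the rounding precision per field
    (keys: ``pct_male``, ``pct_male_by_outcome``, ``pct_mortality_in_positive``,
    ``pct_by_outcome``, ``pathogen_pct``); reported sources mix precisions, so
    the caller states what it wants.
    """
    if len(pheno) == 0:
        raise ValueError("cannot summarize an empty phenotype table")
    validate_phenotype(pheno)
    fd = field_decimals or {}

    def dec(name: str) -> int:
        return fd.get(name, decimals)

    n_total = len(pheno)
    n_by_outcome = pheno["outcome"].value_counts().to_dict()
    pct_by_outcome = {
        k: percent(v, n_total, dec("pct_by_outcome")) for k, v in n_by_outcome.items()
    }

    pct_male: float | None = None
    pct_male_by_outcome: dict[str, float] = {}
    if "sex" in pheno.columns:
        is_male = pheno["sex"].astype(str).str.lower().str.startswith("m")
        pct_male = percent(int(is_male.sum()), n_total, dec("pct_male"))
        for outcome, grp in pheno.groupby("outcome"):
            grp_male = grp["sex"].astype(str).str.lower().str.startswith("m")
            pct_male_by_outcome[str(outcome)] = percent(
                int(grp_male.sum()), len(grp), dec("pct_male_by_outcome")
            )

    pct_mort: float | None = None
    if "mortality" in pheno.columns:
        pos = pheno[pheno["outcome"] == OUTCOME_POSITIVE]
        if len(pos):
            died = pos["mortality"].fillna(False).astype(bool)
            pct_mort = percent(int(died.sum()), len(pos), dec("pct_mortality_in_positive"))

    pathogen_counts: dict[str, int] = {}
    pathogen_pct: dict[str, float] = {}
    if "pathogen" in pheno.columns:
        counts = pheno["pathogen"].dropna()
        counts = counts[counts.astype(str).str.len() > 0].value_counts()
        pathogen_counts = {str(k): int(v) for k, v in counts.items()}
        pathogen_pct = {
            k: percent(v, n_total, dec("pathogen_pct")) for k, v in pathogen_counts.items()
        }

    return CohortSummary(
        n_total=n_total,
        n_by_outcome={str(k): int(v) for k, v in n_by_outcome.items()},
        pct_by_outcome=pct_by_outcome,
        pct_male=pct_male,
        pct_male_by_outcome=pct_male_by_outcome,
        pct_mortality_in_positive=pct_mort,
        pathogen_counts=pathogen_counts,
        pathogen_pct=pathogen_pct,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: dict[str, dict[str, list[Any]]] = {
    "brf": {"n_estimators": [100, 250]},
    "extra_trees": {"n_estimators": [100, 250]},
    "logit": {"C": [0.1, 1.0, 10.0]},
    "gradient_boosting": {"n_estimators": [100], "max_depth": [2, 3]},
    "xgboost": {"max_iter": [100], "l2_regularization": [0.0, 1.0]},
    "easy_ensemble": {"n_estimators": [10]},
}


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Every run writes its resolved config (including the seed) next to its
    outputs so it can be replayed exactly.
    """

    seed: int = 0
    n_folds: int = 5
    n_repeats: int = 10
    fdr_cutoff: float = 0.1
    lfc_cutoff: float = 1.0
    sampler: str = "smote"
    classifier: str = "brf"
    rfe_target: int = 20
    threshold_step: float = 0.001
    threshold: float = 0.5
    grids: dict[str, dict[str, list[Any]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()}
    )
    log2_transform: bool = False
    quantile_normalize: bool = False
    inner_cv: int = 3
    rf_trees: int = 300
    mrmr_k: int = 30
    lasso_cs: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0, 10.0])
    rfe_step_frac: float = 0.1
    rfe_estimator: str = "logit"
    rfe_estimator_trees: int = 50
    clinical_features: list[str] = field(default_factory=lambda: ["severity_score"])
    protect_clinical: bool = True
    global_degs: bool = False
    stability_threshold_pct: float = 60.0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must be in (0, 1)")
        n_steps = 1.0 / self.threshold_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("threshold_step must divide 1 into an integer number of steps")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            warnings.warn(f"ignoring unknown config keys: {sorted(extra)}")
        return cls(**{k: v for k, v in data.items() if k in known})


def child_seed(*keys: int) -> int:
    """Derive a reproducible 32-bit seed from a tuple of integer keys."""
    ss = np.random.SeedSequence(list(int(k) for k in keys))
    return int(ss.generate_state(1)[0])
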