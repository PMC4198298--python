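"""Core in-memory containers.

Expression matrices are plain pandas DataFrames (genes as rows, samples as
columns, values on the log2 scale); clinical tables are DataFrames indexed by
sample id with ``time`` and ``event`` columns followed by covariates.  The
dataclasses here bundle those primitives into the compound objects the
pipeline passes around.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PairedCohort",
    "SurvivalCohort",
    "ScoringModel",
    "RiskAssignment",
    "CoxFit",
    "KMCurve",
    "LogRankResult",
    "ResamplingResult",
    "validate_expression",
    "validate_clinical",
]


def validate_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Check the genes x samples invariants: unique ids, finite values."""
    if expression.index.duplicated().any():
        dup = expression.index[expression.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id: {dup!r}")
    if expression.columns.duplicated().any():
        dup = expression.columns[expression.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    values = expression.to_numpy()
    if values.size and not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValidationError(
            f"non-finite expression value at gene {expression.index[i]!r}, "
            f"sample {expression.columns[j]!r}"
        )
    return expression


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check survival-table invariants: unique ids, time > 0, event in {0,1}."""
    for col in ("time", "event"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    if clinical.index.duplicated().any():
        dup = clinical.index[clinical.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id in clinical table: {dup!r}")
    time = clinical["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValidationError("clinical 'time' must be finite and > 0")
    event = clinical["event"].to_numpy()
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("clinical 'event' must be 0 or 1")
    return clinical


@dataclass
class PairedCohort:
    """Expression of paired normal/tumor samples for one cancer type.

    ``pairs`` has one row per patient with columns ``patient_id``,
    ``normal_sample_id`` and ``tumor_sample_id``, each referring to a column
    of ``expression``.
    """

    cancer: str
    expression: pd.DataFrame
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        validate_expression(self.expression)
        needed = {"patient_id", "normal_sample_id", "tumor_sample_id"}
        missing = needed - set(self.pairs.columns)
        if missing:
            raise ValidationError(f"pairs table missing columns: {sorted(missing)}")
        samples = set(self.expression.columns)
        for col in ("normal_sample_id", "tumor_sample_id"):
            unknown = set(self.pairs[col]) - samples
            if unknown:
                raise ValidationError(
                    f"pairs column {col!r} refers to unknown samples: "
                    f"{sorted(unknown)[:3]}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def differences(self) -> pd.DataFrame:
        """Per-gene within-patient tumor minus normal differences (log2)."""
        tumor = self.expression[self.pairs["tumor_sample_id"].to_numpy()]
        normal = self.expression[self.pairs["normal_sample_id"].to_numpy()]
        diff = tumor.to_numpy() - normal.to_numpy()
        return pd.DataFrame(
            diff, index=self.expression.index, columns=self.pairs["patient_id"].to_numpy()
        )


@dataclass
class SurvivalCohort:
    """Expression plus time-to-event clinical data for one cohort."""

    name: str
    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        validate_expression(self.expression)
        validate_clinical(self.clinical)
        if set(self.expression.columns) != set(self.clinical.index):
            raise ValidationError(
                f"cohort {self.name!r}: expression samples and clinical samples differ"
            )
        # align clinical rows to the expression column order
        self.clinical = self.clinical.loc[self.expression.columns]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.clinical["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)


@dataclass(frozen=True)
class ScoringModel:
    """Frozen risk-scoring system trained on one cohort.

    ``weights`` is indexed by gene with columns ``z`` (per-gene Cox Wald
    statistic from the training cohort), ``mu`` and ``tau`` (training mean and
    SD of that gene's expression, log2 units).  Once built, the model is
    serialized and never refit; validation cohorts are scored with these
    frozen coefficients.
    """

    weights: pd.DataFrame
    training_cohort: str
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("z", "mu", "tau"):
            if col not in self.weights.columns:
                raise ValidationError(f"scoring model missing column {col!r}")
        if self.weights.index.duplicated().any():
            raise ValidationError("scoring model has duplicate gene ids")
        if (self.weights["tau"] <= 0).any():
            bad = self.weights.index[self.weights["tau"] <= 0][0]
            raise ValidationError(f"scoring model tau must be > 0 (gene {bad!r})")

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    def to_json(self) -> str:
        doc = {
            "format": "vagsig-scoring-model",
            "version": 1,
            "training_cohort": self.training_cohort,
            "metadata": dict(self.metadata),
            "gene_order": self.genes,
            "genes": {
                g: {"z": float(r.z), "mu": float(r.mu), "tau": float(r.tau)}
                for g, r in self.weights.iterrows()
            },
        }
        return json.dumps(doc, indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "ScoringModel":
        doc = json.loads(text)
        order = doc["gene_order"]
        weights = pd.DataFrame(
            [[doc["genes"][g][k] for k in ("z", "mu", "tau")] for g in order],
            index=pd.Index(order, name="gene"),
            columns=["z", "mu", "tau"],
        )
        return cls(
            weights=weights,
            training_cohort=doc.get("training_cohort", ""),
            metadata=doc.get("metadata", {}),
        )


@dataclass
class RiskAssignment:
    """Per-sample risk scores and median-dichotomized groups for one cohort.

    ``table`` is indexed by sample id with columns ``score`` (float) and
    ``positive`` (bool; True iff score strictly exceeds the cohort median).
    """

    table: pd.DataFrame
    median: float
    n_genes_used: int
    n_genes_missing: int = 0

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def positive(self) -> pd.Series:
        return self.table["positive"]


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit summary."""

    beta: float
    se: float
    z: float
    p: float
    hr: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CoxFit(HR={self.hr:.3g} [{self.ci_low:.3g}, {self.ci_high:.3g}], "
            f"z={self.z:.3g}, p={self.p:.3g}, n={self.n}, events={self.n_events})"
        )


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve.

    One row per distinct event time: survival probability just after the
    time, number at risk just before it, and the number of events at it.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p: float


@dataclass
class ResamplingResult:
    """Observed statistic against a resampling null.

    ``p_one_tailed`` uses the add-one right-tail estimator
    (1 + #{null >= observed}) / (1 + #null), so it is never exactly zero.
    """

    observed_statistic: float
    null_values: np.ndarray
    p_one_tailed: float
    n_resamples: int
    seed: int
    statistic_name: str
    n_skipped: int = 0

    def summary(self) -> dict[str, float]:
        q = np.quantile(self.null_values, [0.025, 0.25, 0.5, 0.75, 0.975])
        return {
            "observed": float(self.observed_statistic),
            "p_one_tailed": float(self.p_one_tailed),
            "null_mean": float(np.mean(self.null_values)),
            "null_q025": float(q[0]),
            "null_median": float(q[2]),
            "null_q975": float(q[4]),
            "n_resamples": int(self.n_resamples),
            "n_skipped": int(self.n_skipped),
        }
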