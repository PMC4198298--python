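"""Kaplan-Meier estimation, log-rank tests, and Cox regression tables.

This is the evaluation layer: product-limit curves and two-group log-rank
tests for dichotomized risk groups, univariate and multivariate Cox models
(Efron ties), and per-stratum analyses that reuse the cohort-level risk
dichotomization.  KM, log-rank and the multivariate fits are delegated to
lifelines behind this module's surface; the univariate fit shares the
package's own partial-likelihood core.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import CoxFit, KMCurve, LogRankResult
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    ValidationError,
)
from .scoring import fit_univariate_cox

__all__ = [
    "km_estimate",
    "logrank_test",
    "cox_multivariate",
    "stratified_vag_analysis",
    "StratumResult",
]

logger = logging.getLogger(__name__)


def km_estimate(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct *event* time; purely censored times reduce
    the at-risk counts but introduce no step.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValidationError("km_estimate needs at least one observation")
    if np.any(time <= 0):
        raise ValidationError("times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    times = steps.index.to_numpy(dtype=float)
    survival = kmf.survival_function_.loc[times].to_numpy().ravel()
    return KMCurve(
        times=times,
        survival=survival,
        at_risk=steps["at_risk"].to_numpy(dtype=int),
        events=steps["observed"].to_numpy(dtype=int),
    )


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> LogRankResult:
    """Two-group log-rank test (df = 1, two-sided)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 non-empty groups, got {levels.size}")
    if event.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    res = multivariate_logrank_test(time, group, event)
    return LogRankResult(
        chi_square=float(res.test_statistic), df=1, p=float(res.p_value)
    )


def _encode_covariates(
    clinical: pd.DataFrame,
    covariates: list[str],
    categorical: dict[str, str] | None,
) -> pd.DataFrame:
    """Build a numeric design frame; categorical columns need a declared
    reference level (no silent alphabetical defaults)."""
    categorical = categorical or {}
    design = pd.DataFrame(index=clinical.index)
    for col in covariates:
        if col not in clinical.columns:
            raise ValidationError(f"covariate {col!r} not in clinical table")
        series = clinical[col]
        if col in categorical:
            ref = categorical[col]
            levels = series.astype(str).unique()
            if str(ref) not in levels:
                raise ValidationError(
                    f"reference level {ref!r} not a level of {col!r} ({sorted(levels)})"
                )
            for level in sorted(set(levels) - {str(ref)}):
                design[f"{col}[{level} vs {ref}]"] = (
                    series.astype(str) == level
                ).astype(float)
        else:
            if not pd.api.types.is_numeric_dtype(series):
                raise ValidationError(
                    f"covariate {col!r} is non-numeric; declare its reference level"
                )
            design[col] = series.astype(float)
    return design


def cox_multivariate(
    clinical: pd.DataFrame,
    covariates: list[str],
    categorical: dict[str, str] | None = None,
    *,
    ties: str = "efron",
) -> pd.DataFrame:
    """Joint Cox PH fit; one row per encoded covariate.

    ``clinical`` must contain ``time``/``event`` plus the covariate columns.
    Categorical covariates are indicator-coded against the declared reference
    level.  Returns a table with hazard ratio, 95% CI and Wald P per
    covariate.  Collinear designs raise, naming the columns.
    """
    if int(clinical["event"].sum()) < 2:
        raise InsufficientDataError("multivariate Cox needs >= 2 events")
    design = _encode_covariates(clinical, covariates, categorical)
    X = design.to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered) < X.shape[1]:
        # name a minimal offending column for the error message
        for j in range(X.shape[1]):
            sub = centered[:, : j + 1]
            if np.linalg.matrix_rank(sub) < j + 1:
                raise DegenerateDesignError(
                    f"collinear covariate column {design.columns[j]!r}"
                )
        raise DegenerateDesignError("collinear design matrix")
    frame = design.copy()
    frame["time"] = clinical["time"].to_numpy(dtype=float)
    frame["event"] = clinical["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame, duration_col="time", event_col="event")
    summary = cph.summary
    out = pd.DataFrame(
        {
            "covariate": summary.index,
            "hr": summary["exp(coef)"].to_numpy(),
            "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
            "z": summary["z"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return out


@dataclass
class StratumResult:
    """Per-stratum evaluation of the dichotomized risk groups."""

    stratum: str
    fit: CoxFit
    logrank: LogRankResult
    km_positive: KMCurve
    km_negative: KMCurve
    n: int
    n_events: int


def stratified_vag_analysis(
    clinical: pd.DataFrame,
    positive: pd.Series,
    stratum_variable: str,
) -> dict[str, StratumResult]:
    """Evaluate risk-group separation within each level of a stratum variable.

    The cohort-level dichotomization (``positive``) is reused inside the
    strata — patients are stratified, the scoring is not redone.  Strata with
    fewer than 2 events, or with only one risk group present, are skipped
    with a warning.
    """
    if stratum_variable not in clinical.columns:
        raise ValidationError(f"stratum variable {stratum_variable!r} not in clinical table")
    positive = positive.reindex(clinical.index)
    if positive.isna().any():
        raise ValidationError("positive indicator missing for some samples")
    results: dict[str, StratumResult] = {}
    for level, sub in clinical.groupby(clinical[stratum_variable].astype(str)):
        grp = positive.loc[sub.index].to_numpy(dtype=bool)
        events = int(sub["event"].sum())
        if events < 2 or len(np.unique(grp)) < 2:
            logger.warning(
                "stratified analysis: skipping stratum %r (%d events, %d groups)",
                level, events, len(np.unique(grp)),
            )
            continue
        fit = fit_univariate_cox(grp.astype(float), sub)
        lr = logrank_test(sub["time"].to_numpy(), sub["event"].to_numpy(), grp)
        km_pos = km_estimate(sub["time"].to_numpy()[grp], sub["event"].to_numpy()[grp])
        km_neg = km_estimate(sub["time"].to_numpy()[~grp], sub["event"].to_numpy()[~grp])
        results[str(level)] = StratumResult(
            stratum=str(level),
            fit=fit,
            logrank=lr,
            km_positive=km_pos,
            km_negative=km_neg,
            n=len(sub),
            n_events=events,
        )
    return results
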