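"""Wald-weighted standardized risk scoring.

For each signature gene i a univariate Cox model of recurrence-free survival
on that gene's expression is fit on the training cohort; the Wald statistic
Z_i = beta_i / se_i becomes the gene's weight.  A patient's risk score is

    S = sum_i Z_i * (e_i - mu_i) / tau_i

where e_i is the patient's expression of gene i and mu_i, tau_i are the mean
and SD of gene i across all training samples.  The scoring system (Z, mu,
tau) is frozen on the training cohort; scored cohorts are split at their own
median score, with "positive" meaning strictly above the median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CoxFit, RiskAssignment, ScoringModel, SurvivalCohort
from .cox import cox_fit_many
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "fit_univariate_cox",
    "build_scoring_model",
    "compute_risk_scores",
    "dichotomize",
]

logger = logging.getLogger(__name__)


def fit_univariate_cox(
    expression: np.ndarray | pd.Series,
    clinical: pd.DataFrame,
    *,
    ties: str = "efron",
) -> CoxFit:
    """Univariate Cox PH fit of survival on one covariate.

    ``clinical`` needs ``time`` and ``event`` columns; ``expression`` is the
    per-sample covariate in the same order.  Returns the partial-likelihood
    estimate with Wald z, HR and normal-approximation 95% CI.
    """
    x = np.asarray(expression, dtype=float)
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    if x.shape[0] != time.shape[0]:
        raise ValidationError("expression and clinical lengths differ")
    if not np.isfinite(x).all():
        raise ValidationError("expression contains non-finite values")
    if event.sum() < 2:
        raise InsufficientDataError("univariate Cox fit needs >= 2 events")
    if x.std() == 0.0:
        raise DegenerateDataError("covariate has zero variance")
    res = cox_fit_many(x[:, None], time, event, ties=ties)
    beta = float(res["beta"][0])
    se = float(res["se"][0])
    return CoxFit(
        beta=beta,
        se=se,
        z=float(res["z"][0]),
        p=float(res["p"][0]),
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        n=int(res["n"]),
        n_events=int(res["n_events"]),
    )


def build_scoring_model(
    training: SurvivalCohort,
    signature: list[str] | set[str],
    *,
    ties: str = "efron",
    name: str | None = None,
) -> ScoringModel:
    """Fit per-gene Cox weights on the training cohort and freeze the scorer.

    Genes missing from the training matrix are skipped (hard error if more
    than half are missing); genes with constant expression are dropped with a
    warning.  mu and tau are the per-gene mean and SD (ddof=1) over all
    training samples.
    """
    signature = sorted(set(signature))
    if not signature:
        raise ValidationError("empty signature")
    present = [g for g in signature if g in training.expression.index]
    n_missing = len(signature) - len(present)
    if n_missing > 0.5 * len(signature):
        raise InsufficientDataError(
            f"{n_missing}/{len(signature)} signature genes missing from training cohort"
        )
    if n_missing:
        logger.warning("build_scoring_model: %d signature genes missing", n_missing)
    X = training.expression.loc[present].to_numpy(dtype=float).T  # samples x genes
    mu = X.mean(axis=0)
    tau = X.std(axis=0, ddof=1)
    ok = tau > 0
    if not ok.any():
        raise DegenerateDataError("all signature genes are constant in training")
    if (~ok).any():
        dropped = [g for g, k in zip(present, ok) if not k]
        logger.warning(
            "build_scoring_model: dropping %d constant genes: %s",
            len(dropped), dropped[:5],
        )
    res = cox_fit_many(
        X[:, ok], training.time, training.event, ties=ties
    )
    genes = [g for g, k in zip(present, ok) if k]
    weights = pd.DataFrame(
        {"z": res["z"], "mu": mu[ok], "tau": tau[ok]},
        index=pd.Index(genes, name="gene"),
    )
    bad = weights["z"].isna()
    if bad.any():
        logger.warning(
            "build_scoring_model: dropping %d genes with degenerate Cox fits",
            int(bad.sum()),
        )
        weights = weights[~bad]
    if weights.empty:
        raise DegenerateDataError("no signature gene admitted a Cox fit")
    return ScoringModel(
        weights=weights,
        training_cohort=name if name is not None else training.name,
        metadata={"n_signature": len(signature), "n_fit": len(weights)},
    )


def compute_risk_scores(
    model: ScoringModel,
    cohort: SurvivalCohort,
    *,
    restandardize_per_cohort: bool = False,
) -> RiskAssignment:
    """Score every sample of ``cohort`` with a frozen model and dichotomize.

    Model genes absent from the cohort are dropped from the sum without
    reweighting (count reported).  With ``restandardize_per_cohort`` the
    scaling coefficients mu, tau are recomputed on the scored cohort itself
    (cross-platform variant) instead of using the frozen training values.
    The positive/negative split uses the scored cohort's own median score,
    strictly-greater-than convention.
    """
    genes = [g for g in model.genes if g in cohort.expression.index]
    n_missing = len(model.genes) - len(genes)
    if not genes:
        raise ValidationError("no model genes present in cohort")
    if n_missing:
        logger.warning(
            "compute_risk_scores: %d model genes missing from cohort %r",
            n_missing, cohort.name,
        )
    E = cohort.expression.loc[genes].to_numpy(dtype=float)  # genes x samples
    w = model.weights.loc[genes]
    z = w["z"].to_numpy()
    if restandardize_per_cohort:
        mu = E.mean(axis=1)
        tau = E.std(axis=1, ddof=1)
        if np.any(tau == 0):
            keep = tau > 0
            E, z, mu, tau = E[keep], z[keep], mu[keep], tau[keep]
            if E.size == 0:
                raise DegenerateDataError("all model genes constant in cohort")
    else:
        mu = w["mu"].to_numpy()
        tau = w["tau"].to_numpy()
    scores = pd.Series(
        z @ ((E - mu[:, None]) / tau[:, None]),
        index=cohort.expression.columns,
        name="score",
    )
    positive, median = dichotomize(scores)
    table = pd.DataFrame({"score": scores, "positive": positive})
    return RiskAssignment(
        table=table, median=median, n_genes_used=len(genes), n_genes_missing=n_missing
    )


def dichotomize(scores: pd.Series | np.ndarray) -> tuple[pd.Series, float]:
    """Split scores at their median; positive iff strictly greater.

    Ties at the median go to the negative group.  Returns the boolean
    positive indicator and the median used.
    """
    values = np.asarray(scores, dtype=float)
    if values.size < 2:
        raise ValidationError("dichotomize needs >= 2 samples")
    median = float(np.median(values))
    positive = values > median
    if not positive.any():
        import warnings

        if np.all(values == values[0]):
            warnings.warn("all risk scores equal; every sample is negative", stacklevel=2)
    if isinstance(scores, pd.Series):
        return pd.Series(positive, index=scores.index, name="positive"), median
    return pd.Series(positive, name="positive"), median
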