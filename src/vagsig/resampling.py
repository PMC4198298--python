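"""Random-signature resampling nulls.

Three questions share one machinery — is the observed signature better than
random same-size gene sets?

* **Prognostic power**: the statistic is the Wald z of the dichotomized risk
  group from a univariate Cox fit in the validation cohort, where the whole
  scoring pipeline (per-gene Cox weights on the training cohort, frozen
  scaling, median split) is re-run from scratch for every random signature.
* **Pooled prognostic power** against a reference pool (e.g. cancer-related
  genes outside the curated interacting set): the statistic is the sum of
  the validation Wald z over several cohort pairs.
* **Co-expression coherence**: the statistic is the sum of the tree-ensemble
  weighted adjacency matrix of the gene set.

All empirical P-values are one-tailed (right tail) with the add-one
estimator (1 + #{null >= observed}) / (1 + N), so P is never exactly zero.
Degenerate resamples (e.g. every score identical) are skipped and counted; a
skip fraction above 5% aborts the run.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import ResamplingResult, SurvivalCohort
from .cox import cox_fit_many
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    NumericalError,
    ValidationError,
)
from .scoring import build_scoring_model, compute_risk_scores

__all__ = [
    "random_signatures",
    "signature_wald_z",
    "prognostic_null_test",
    "pooled_sum_z_test",
    "coherence_null_test",
]

logger = logging.getLogger(__name__)

MAX_SKIP_FRACTION = 0.05


def random_signatures(
    pool: Sequence[str] | set[str], size: int, n: int, seed: int
) -> list[list[str]]:
    """Draw ``n`` uniform same-size gene sets without replacement from a pool."""
    pool = sorted(set(pool))
    if size > len(pool):
        raise ValidationError(f"signature size {size} exceeds pool size {len(pool)}")
    if n < 1:
        raise ValidationError("need n >= 1 resamples")
    rng = np.random.default_rng(seed)
    return [list(rng.choice(pool, size=size, replace=False)) for _ in range(n)]


def _group_wald_z(positive: np.ndarray, cohort: SurvivalCohort) -> float:
    """Wald z of the binary risk-group covariate in a univariate Cox fit."""
    x = positive.astype(float)
    if x.std() == 0.0:
        raise DegenerateDataError("risk groups are constant")
    if cohort.event.sum() < 2:
        raise InsufficientDataError("need >= 2 events")
    res = cox_fit_many(x[:, None], cohort.time, cohort.event)
    z = float(res["z"][0])
    if not np.isfinite(z):
        raise DegenerateDataError("degenerate group Cox fit")
    return z


def signature_wald_z(
    signature: Iterable[str],
    training: SurvivalCohort,
    validation: SurvivalCohort,
    *,
    restandardize_per_cohort: bool = False,
) -> float:
    """Full train -> score -> dichotomize -> Cox pipeline for one signature.

    Returns the validation-cohort Wald z of the dichotomized risk group.
    """
    model = build_scoring_model(training, list(signature))
    assignment = compute_risk_scores(
        model, validation, restandardize_per_cohort=restandardize_per_cohort
    )
    return _group_wald_z(assignment.positive.to_numpy(), validation)


def _empirical_result(
    observed: float,
    null_values: list[float],
    n_resamples: int,
    n_skipped: int,
    seed: int,
    statistic_name: str,
) -> ResamplingResult:
    if n_skipped > MAX_SKIP_FRACTION * n_resamples:
        raise NumericalError(
            f"{n_skipped}/{n_resamples} resamples degenerate (> {MAX_SKIP_FRACTION:.0%})"
        )
    null = np.asarray(null_values, dtype=float)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + null.size)
    return ResamplingResult(
        observed_statistic=float(observed),
        null_values=null,
        p_one_tailed=float(p),
        n_resamples=n_resamples,
        seed=seed,
        statistic_name=statistic_name,
        n_skipped=n_skipped,
    )


def prognostic_null_test(
    signature: Iterable[str],
    training: SurvivalCohort,
    validation: SurvivalCohort,
    pool: Sequence[str] | set[str],
    n_resamples: int = 1000,
    seed: int = 0,
    *,
    restandardize_per_cohort: bool = False,
) -> ResamplingResult:
    """Is the signature's prognostic power better than random signatures?

    The observed statistic and every null statistic go through the identical
    end-to-end pipeline; the null draws same-size signatures from ``pool``.
    """
    signature = sorted(set(signature))
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    observed = signature_wald_z(
        signature, training, validation,
        restandardize_per_cohort=restandardize_per_cohort,
    )
    draws = random_signatures(pool, len(signature), n_resamples, seed)
    null_values: list[float] = []
    n_skipped = 0
    for genes in draws:
        try:
            null_values.append(
                signature_wald_z(
                    genes, training, validation,
                    restandardize_per_cohort=restandardize_per_cohort,
                )
            )
        except (DegenerateDataError, InsufficientDataError) as exc:
            n_skipped += 1
            logger.debug("skipping degenerate resample: %s", exc)
    return _empirical_result(
        observed, null_values, n_resamples, n_skipped, seed, "validation_wald_z"
    )


def pooled_sum_z_test(
    signature: Iterable[str],
    cohort_pairs: Sequence[tuple[SurvivalCohort, SurvivalCohort]],
    pool: Sequence[str] | set[str],
    n_resamples: int = 1000,
    seed: int = 0,
    *,
    restandardize_per_cohort: bool = False,
) -> ResamplingResult:
    """Sum-of-Wald-z test across several (training, validation) pairs.

    Each random draw uses one gene set evaluated in every cohort pair, so the
    null respects the between-cohort dependence of a shared signature.
    """
    if not cohort_pairs:
        raise ValidationError("need >= 1 cohort pair")
    signature = sorted(set(signature))
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")

    def sum_z(genes: Iterable[str]) -> float:
        return sum(
            signature_wald_z(
                genes, tr, va, restandardize_per_cohort=restandardize_per_cohort
            )
            for tr, va in cohort_pairs
        )

    observed = sum_z(signature)
    draws = random_signatures(pool, len(signature), n_resamples, seed)
    null_values: list[float] = []
    n_skipped = 0
    for genes in draws:
        try:
            null_values.append(sum_z(genes))
        except (DegenerateDataError, InsufficientDataError) as exc:
            n_skipped += 1
            logger.debug("skipping degenerate resample: %s", exc)
    return _empirical_result(
        observed, null_values, n_resamples, n_skipped, seed, "sum_validation_wald_z"
    )


def coherence_null_test(
    signature: Iterable[str],
    expression: pd.DataFrame,
    pool: Sequence[str] | set[str],
    n_resamples: int = 1000,
    seed: int = 0,
    *,
    n_trees: int = 100,
    max_features: int | float | str = "sqrt",
) -> ResamplingResult:
    """Is the signature's co-expression coherence better than random sets?

    The statistic is the sum of the tree-ensemble weighted adjacency matrix
    inferred on ``expression`` restricted to the gene set.
    """
    from .network import coherence_statistic, infer_adjacency

    signature = sorted(set(signature))
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    missing = [g for g in signature if g not in expression.index]
    if missing:
        raise ValidationError(f"signature genes missing from expression: {missing[:3]}")
    rng = np.random.default_rng(seed)

    def coherence(genes: Sequence[str]) -> float:
        w = infer_adjacency(
            expression.loc[list(genes)],
            n_trees=n_trees,
            max_features=max_features,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        return coherence_statistic(w)

    observed = coherence(signature)
    draws = random_signatures(pool, len(signature), n_resamples, seed)
    null_values = [coherence(genes) for genes in draws]
    return _empirical_result(
        observed, null_values, n_resamples, 0, seed, "adjacency_sum"
    )
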