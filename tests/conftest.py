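"""Shared fixtures: small seeded synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from vagsig import (
    PairedCohort,
    SurvSimConfig,
    SurvivalCohort,
    generate_survival_cohort,
)


def make_paired_cohort(
    differences: np.ndarray,
    cancer: str = "testis",
    gene_ids: list[str] | None = None,
    baseline: float = 8.0,
    seed: int = 0,
) -> PairedCohort:
    """Build a paired cohort whose tumor-normal differences are exactly
    ``differences`` (genes x patients)."""
    differences = np.atleast_2d(np.asarray(differences, dtype=float))
    n_genes, n_pairs = differences.shape
    rng = np.random.default_rng(seed)
    genes = gene_ids or [f"g{i}" for i in range(n_genes)]
    normal = baseline + rng.normal(size=(n_genes, n_pairs))
    tumor = normal + differences
    patients = [f"P{i}" for i in range(n_pairs)]
    expr = pd.DataFrame(
        np.hstack([normal, tumor]),
        index=genes,
        columns=[f"{p}_N" for p in patients] + [f"{p}_T" for p in patients],
    )
    pairs = pd.DataFrame(
        {
            "patient_id": patients,
            "normal_sample_id": [f"{p}_N" for p in patients],
            "tumor_sample_id": [f"{p}_T" for p in patients],
        }
    )
    return PairedCohort(cancer=cancer, expression=expr, pairs=pairs)


def make_survival_cohort(
    n: int = 120,
    seed: int = 0,
    betas: dict[str, float] | None = None,
    signature: tuple[str, ...] = ("G0001", "G0002", "G0003"),
    n_genes: int = 30,
    loading: float = 0.0,
    censoring_rate: float = 0.05,
) -> SurvivalCohort:
    cfg = SurvSimConfig(
        n_samples=n,
        n_genes=n_genes,
        signature_genes=signature,
        betas=betas or {},
        latent_factor_loading=loading,
        baseline_hazard=0.05,
        censoring_rate=censoring_rate,
        admin_censor_time=100.0,
        seed=seed,
    )
    cohort, _ = generate_survival_cohort(cfg)
    return cohort


@pytest.fixture
def small_survival_cohort() -> SurvivalCohort:
    return make_survival_cohort(n=120, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
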