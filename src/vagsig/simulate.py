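"""Synthetic cohort generators with known ground truth.

Two study designs are emulated directly on the log2 expression scale:

* **Paired normal/tumor cohorts** across several cancer types, with planted
  differentially expressed genes whose perturbation direction agrees across a
  chosen number of cancers.  The paired structure is an additive per-patient,
  per-gene random effect shared between the normal and tumor sample, so the
  within-patient difference cancels it — exactly the situation in which the
  paired t-test beats the unpaired one.

* **Survival cohorts** whose hazard follows an exponential proportional-
  hazards model with linear predictor over a set of signature genes.
  Signature-gene expression follows a one-latent-factor model (pairwise
  correlation = loading^2); remaining genes are independent noise.  Censoring
  is the minimum of an independent exponential censoring time and an
  administrative cut-off.

Every generator returns the ground truth next to the data, and is a pure
function of its config (including the mandatory seed): same config, same
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import PairedCohort, SurvivalCohort
from .errors import ConfigurationError

__all__ = [
    "PairedSimConfig",
    "SurvSimConfig",
    "generate_paired_cohorts",
    "generate_survival_cohort",
    "default_gene_ids",
]


def default_gene_ids(n_genes: int) -> list[str]:
    """Synthetic gene identifiers G0001, G0002, ..."""
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


# effect spec per DE gene: a single signed log2 effect applied in
# `accordant_in` cancers, or an explicit {cancer: effect} mapping
EffectSpec = float | Mapping[str, float]


@dataclass
class PairedSimConfig:
    """Configuration for the multi-cancer paired normal/tumor simulator.

    Parameters
    ----------
    de_genes
        Mapping gene id -> effect.  A float effect means "this signed log2
        shift in ``accordant_in`` randomly chosen cancers"; a mapping gives
        explicit per-cancer signed effects (useful to plant discordant genes).
    pair_effect_sd
        SD of the per-patient random effect shared by the normal and tumor
        sample of a patient (log2 units).
    noise_sd
        Residual SD per sample (log2 units).
    """

    n_cancers: int = 6
    n_genes: int = 1000
    n_patients_per_cancer: int = 30
    de_genes: Mapping[str, EffectSpec] = field(default_factory=dict)
    accordant_in: int = 5
    pair_effect_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0
    cancer_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_cancers < 1 or self.n_genes < 1 or self.n_patients_per_cancer < 1:
            raise ConfigurationError("counts must be positive")
        if self.pair_effect_sd <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("SDs must be > 0")
        if len(self.de_genes) > self.n_genes:
            raise ConfigurationError("more DE genes than genes")
        needs_accordant = any(
            not isinstance(v, Mapping) for v in self.de_genes.values()
        )
        if needs_accordant and not 1 <= self.accordant_in <= self.n_cancers:
            raise ConfigurationError("accordant_in must be in [1, n_cancers]")
        if self.cancer_labels is not None and len(self.cancer_labels) != self.n_cancers:
            raise ConfigurationError("cancer_labels length must equal n_cancers")

    @property
    def labels(self) -> list[str]:
        if self.cancer_labels is not None:
            return list(self.cancer_labels)
        return [f"cancer{i + 1}" for i in range(self.n_cancers)]


def generate_paired_cohorts(
    config: PairedSimConfig,
) -> tuple[list[PairedCohort], pd.DataFrame]:
    """Simulate one paired cohort per cancer type.

    The tumor value of gene g in patient p is
    ``baseline + patient_effect + effect(g, cancer) + noise``; the normal
    value omits the effect term.

    Returns
    -------
    cohorts
        One :class:`PairedCohort` per cancer.
    truth
        DataFrame with one row per (DE gene, perturbed cancer): columns
        ``gene``, ``cancer``, ``effect``, ``direction``.
    """
    rng = np.random.default_rng(config.seed)
    genes = default_gene_ids(config.n_genes)
    gene_set = set(genes)
    labels = config.labels

    unknown = [g for g in config.de_genes if g not in gene_set]
    if unknown:
        raise ConfigurationError(f"de_genes not in gene universe: {unknown[:3]}")

    # resolve per-gene, per-cancer effects (deterministic given seed)
    effects: dict[str, dict[str, float]] = {}
    for g in sorted(config.de_genes):
        spec = config.de_genes[g]
        if isinstance(spec, Mapping):
            bad = set(spec) - set(labels)
            if bad:
                raise ConfigurationError(f"unknown cancer label in de_genes[{g!r}]: {sorted(bad)}")
            effects[g] = {c: float(v) for c, v in spec.items()}
        else:
            chosen = rng.choice(labels, size=config.accordant_in, replace=False)
            effects[g] = {c: float(spec) for c in chosen}

    truth_rows = [
        {
            "gene": g,
            "cancer": c,
            "effect": v,
            "direction": "up" if v > 0 else ("down" if v < 0 else "none"),
        }
        for g, per_cancer in effects.items()
        for c, v in per_cancer.items()
    ]
    truth = pd.DataFrame(truth_rows, columns=["gene", "cancer", "effect", "direction"])

    gene_pos = {g: i for i, g in enumerate(genes)}
    G, P = config.n_genes, config.n_patients_per_cancer
    cohorts = []
    for cancer in labels:
        eff = np.zeros(G)
        for g, per_cancer in effects.items():
            if cancer in per_cancer:
                eff[gene_pos[g]] = per_cancer[cancer]
        patient_effect = rng.normal(0.0, config.pair_effect_sd, size=(G, P))
        normal = (
            config.baseline_mean
            + patient_effect
            + rng.normal(0.0, config.noise_sd, size=(G, P))
        )
        tumor = (
            config.baseline_mean
            + patient_effect
            + eff[:, None]
            + rng.normal(0.0, config.noise_sd, size=(G, P))
        )
        patients = [f"{cancer}_P{p:03d}" for p in range(1, P + 1)]
        normal_ids = [f"{p}_N" for p in patients]
        tumor_ids = [f"{p}_T" for p in patients]
        expr = pd.DataFrame(
            np.hstack([normal, tumor]),
            index=pd.Index(genes, name="gene"),
            columns=normal_ids + tumor_ids,
        )
        pairs = pd.DataFrame(
            {
                "patient_id": patients,
                "normal_sample_id": normal_ids,
                "tumor_sample_id": tumor_ids,
            }
        )
        cohorts.append(PairedCohort(cancer=cancer, expression=expr, pairs=pairs))
    return cohorts, truth


@dataclass
class SurvSimConfig:
    """Configuration for the proportional-hazards survival simulator.

    ``betas`` maps signature gene ids to true log-hazard coefficients per
    unit of (log2) expression; genes absent from the mapping have beta 0.
    ``latent_factor_loading`` is the loading lambda of the shared factor
    among signature genes, giving pairwise correlation lambda^2.
    """

    n_samples: int = 300
    n_genes: int = 200
    signature_genes: Sequence[str] = ()
    betas: Mapping[str, float] = field(default_factory=dict)
    latent_factor_loading: float = 0.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.05
    admin_censor_time: float = 120.0
    baseline_mean: float = 8.0
    seed: int = 0
    name: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ConfigurationError("counts must be positive (n_samples >= 2)")
        if not 0.0 <= self.latent_factor_loading < 1.0:
            raise ConfigurationError("latent_factor_loading must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ConfigurationError("admin_censor_time must be > 0")
        sig = set(self.signature_genes)
        if len(sig) != len(tuple(self.signature_genes)):
            raise ConfigurationError("signature_genes contains duplicates")
        extra = set(self.betas) - sig
        if extra:
            raise ConfigurationError(f"betas for non-signature genes: {sorted(extra)[:3]}")


def generate_survival_cohort(
    config: SurvSimConfig,
) -> tuple[SurvivalCohort, pd.Series]:
    """Simulate one survival cohort plus its true coefficient vector.

    Expression of each signature gene g is
    ``baseline + lambda * F + sqrt(1 - lambda^2) * eps_g`` (unit marginal
    variance); other genes are ``baseline + eps``.  Event times are
    exponential with rate ``baseline_hazard * exp(sum_g beta_g * (x_g -
    baseline))``; censoring is the minimum of an exponential censoring time
    and ``admin_censor_time``.
    """
    rng = np.random.default_rng(config.seed)
    genes = default_gene_ids(config.n_genes)
    gene_set = set(genes)
    missing = [g for g in config.signature_genes if g not in gene_set]
    if missing:
        raise ConfigurationError(f"signature genes not in gene universe: {missing[:3]}")

    G, N = config.n_genes, config.n_samples
    lam = config.latent_factor_loading
    expr = config.baseline_mean + rng.normal(0.0, 1.0, size=(G, N))
    sig_idx = [genes.index(g) for g in config.signature_genes]
    if sig_idx and lam > 0:
        factor = rng.normal(0.0, 1.0, size=N)
        eps = rng.normal(0.0, 1.0, size=(len(sig_idx), N))
        expr[sig_idx, :] = (
            config.baseline_mean + lam * factor[None, :] + np.sqrt(1 - lam * lam) * eps
        )

    beta = pd.Series(0.0, index=pd.Index(genes, name="gene"), name="beta")
    for g, b in config.betas.items():
        beta[g] = float(b)
    eta = beta.to_numpy() @ (expr - config.baseline_mean)

    # unit-exponential draws scaled by the rates, so that at a fixed seed the
    # censoring fraction is monotone in censoring_rate
    u_event = rng.exponential(1.0, size=N)
    u_cens = rng.exponential(1.0, size=N)
    t_event = u_event / (config.baseline_hazard * np.exp(eta))
    t_cens = (
        u_cens / config.censoring_rate if config.censoring_rate > 0 else np.full(N, np.inf)
    )
    t_cens = np.minimum(t_cens, config.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    samples = [f"S{i:04d}" for i in range(1, N + 1)]
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    clinical = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(samples, name="sample_id")
    )
    cohort = SurvivalCohort(name=config.name, expression=expression, clinical=clinical)
    return cohort, beta
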