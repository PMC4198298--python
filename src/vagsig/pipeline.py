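"""End-to-end orchestration of a fully synthetic signature study.

``run_pipeline`` executes the stages in the order the analysis dictates —
simulate paired and survival cohorts, derive the signature by cross-cancer
differential expression, train the frozen scoring model, evaluate survival
separation in the validation cohort, run the resampling nulls, and the
network-coherence test — writing per-stage TSV/JSON artifacts plus a run
manifest (inputs, seeds, checksums, timings).  Every stochastic stage gets
its own seed fanned out from the single run seed by a fixed splitting rule,
so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import SurvivalCohort
from .de import SelectionRule, de_test_cohorts, select_common_de
from .errors import ConfigurationError, DependencyError
from .io import (
    read_clinical,
    read_expression,
    read_gene_list,
    read_scoring_model,
    write_clinical,
    write_expression,
    write_gene_list,
    write_scoring_model,
)
from .resampling import coherence_null_test, prognostic_null_test
from .scoring import build_scoring_model, compute_risk_scores, fit_univariate_cox
from .simulate import (
    PairedSimConfig,
    SurvSimConfig,
    default_gene_ids,
    generate_paired_cohorts,
    generate_survival_cohort,
)
from .survival import km_estimate, logrank_test

__all__ = ["RunConfig", "run_pipeline", "report"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "signature", "train", "evaluate", "resample", "network")


def stage_seed(seed: int, stage: str) -> int:
    """Fixed seed-splitting rule: one run seed fans out per stage."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run.

    The defaults describe a desk-scale study: six paired cohorts of 30
    patients over 1,000 genes with 50 accordant DE genes (log2 effect 1.0 in
    5 of 6 cancers), and 300/300-sample training/validation survival cohorts
    in which 10 of the planted signature genes carry log hazard ratio 0.4
    per SD with latent-factor loading 0.5.
    """

    outdir: str = "vagsig_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # paired simulation
    n_genes: int = 1000
    n_cancers: int = 6
    n_pairs: int = 30
    n_de_genes: int = 50
    de_effect: float = 1.0
    accordant_in: int = 5
    pair_effect_sd: float = 0.5
    noise_sd: float = 0.5
    # survival simulation
    n_train: int = 300
    n_validation: int = 300
    n_prognostic: int = 10
    prognostic_beta: float = 0.4
    latent_loading: float = 0.5
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.01
    admin_censor_time: float = 120.0
    # selection / scoring / resampling
    alpha: float = 0.05
    min_cancers: int = 4
    restandardize_per_cohort: bool = False
    n_resamples: int = 200
    coherence_resamples: int = 50
    coherence_genes: int = 15
    n_trees: int = 25

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if self.n_de_genes > self.n_genes:
            raise ConfigurationError("n_de_genes exceeds n_genes")
        if self.n_prognostic > self.n_de_genes:
            raise ConfigurationError("n_prognostic exceeds n_de_genes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Mutable state threaded through the stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, Any] = {
            "package": "vagsig",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "stage_seeds": {s: stage_seed(config.seed, s) for s in ALL_STAGES},
            "stages": {},
        }
        self.paired = None
        self.truth = None
        self.training: SurvivalCohort | None = None
        self.validation: SurvivalCohort | None = None
        self.true_beta = None
        self.signature: list[str] | None = None
        self.model = None
        self.assignment = None

    def record(self, stage: str, outputs: list[Path], extra: dict | None = None,
               elapsed: float = 0.0) -> None:
        self.manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
            "elapsed_seconds": round(elapsed, 3),
            **(extra or {}),
        }


def _stage_simulate(run: _Run) -> list[Path]:
    cfg = run.config
    seed = stage_seed(cfg.seed, "simulate")
    genes = default_gene_ids(cfg.n_genes)
    de_genes = {g: cfg.de_effect for g in genes[: cfg.n_de_genes]}
    paired_cfg = PairedSimConfig(
        n_cancers=cfg.n_cancers,
        n_genes=cfg.n_genes,
        n_patients_per_cancer=cfg.n_pairs,
        de_genes=de_genes,
        accordant_in=cfg.accordant_in,
        pair_effect_sd=cfg.pair_effect_sd,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    run.paired, run.truth = generate_paired_cohorts(paired_cfg)

    signature_genes = genes[: cfg.n_de_genes]
    betas = {g: cfg.prognostic_beta for g in signature_genes[: cfg.n_prognostic]}
    common = dict(
        n_genes=cfg.n_genes,
        signature_genes=signature_genes,
        betas=betas,
        latent_factor_loading=cfg.latent_loading,
        baseline_hazard=cfg.baseline_hazard,
        censoring_rate=cfg.censoring_rate,
        admin_censor_time=cfg.admin_censor_time,
    )
    run.training, run.true_beta = generate_survival_cohort(
        SurvSimConfig(n_samples=cfg.n_train, seed=seed + 1, name="training", **common)
    )
    run.validation, _ = generate_survival_cohort(
        SurvSimConfig(n_samples=cfg.n_validation, seed=seed + 2, name="validation", **common)
    )

    out = run.outdir
    paths = []
    for cohort in run.paired:
        p = out / f"paired_{cohort.cancer}_expression.tsv"
        write_expression(cohort.expression, p)
        paths.append(p)
        q = out / f"paired_{cohort.cancer}_pairs.tsv"
        cohort.pairs.to_csv(q, sep="\t", index=False)
        paths.append(q)
    p = out / "de_ground_truth.tsv"
    run.truth.to_csv(p, sep="\t", index=False)
    paths.append(p)
    for cohort in (run.training, run.validation):
        p = out / f"{cohort.name}_expression.tsv"
        write_expression(cohort.expression, p)
        paths.append(p)
        q = out / f"{cohort.name}_clinical.tsv"
        write_clinical(cohort.clinical, q)
        paths.append(q)
    p = out / "true_beta.tsv"
    run.true_beta.to_frame().to_csv(p, sep="\t")
    paths.append(p)
    return paths


def _require_simulated(run: _Run) -> None:
    if run.training is not None:
        return
    out = run.outdir
    needed = ["training_expression.tsv", "training_clinical.tsv",
              "validation_expression.tsv", "validation_clinical.tsv"]
    if not all((out / n).exists() for n in needed):
        raise DependencyError(
            "stage requires simulated cohorts; run the 'simulate' stage first"
        )
    run.training = SurvivalCohort(
        "training",
        read_expression(out / "training_expression.tsv"),
        read_clinical(out / "training_clinical.tsv"),
    )
    run.validation = SurvivalCohort(
        "validation",
        read_expression(out / "validation_expression.tsv"),
        read_clinical(out / "validation_clinical.tsv"),
    )


def _stage_signature(run: _Run) -> list[Path]:
    cfg = run.config
    if run.paired is None:
        raise DependencyError("'signature' stage requires the 'simulate' stage")
    results = de_test_cohorts(run.paired)
    rule = SelectionRule(alpha=cfg.alpha, min_cancers=cfg.min_cancers)
    run.signature = sorted(select_common_de(results, rule))
    p1 = run.outdir / "de_results.tsv"
    results.to_csv(p1, sep="\t", index=False, float_format="%.6g")
    p2 = run.outdir / "signature.txt"
    write_gene_list(run.signature, p2, header="derived signature")
    return [p1, p2]


def _stage_train(run: _Run) -> list[Path]:
    _require_simulated(run)
    if run.signature is None:
        sig_path = run.outdir / "signature.txt"
        if not sig_path.exists():
            raise DependencyError("'train' stage requires a signature (run 'signature')")
        run.signature = read_gene_list(sig_path)
    run.model = build_scoring_model(run.training, run.signature)
    p = run.outdir / "scoring_model.json"
    write_scoring_model(run.model, p)
    return [p]


def _stage_evaluate(run: _Run) -> list[Path]:
    cfg = run.config
    _require_simulated(run)
    if run.model is None:
        model_path = run.outdir / "scoring_model.json"
        if not model_path.exists():
            raise DependencyError("'evaluate' stage requires a trained model (run 'train')")
        run.model = read_scoring_model(model_path)
    paths = []
    rows = []
    for cohort in (run.training, run.validation):
        assignment = compute_risk_scores(
            run.model, cohort, restandardize_per_cohort=cfg.restandardize_per_cohort
        )
        if cohort.name == "validation":
            run.assignment = assignment
        p = run.outdir / f"{cohort.name}_scores.tsv"
        table = assignment.table.copy()
        table["group"] = np.where(table["positive"], "positive", "negative")
        table[["score", "group"]].to_csv(p, sep="\t", float_format="%.10g")
        paths.append(p)
        grp = assignment.positive.to_numpy()
        fit = fit_univariate_cox(grp.astype(float), cohort.clinical)
        lr = logrank_test(cohort.time, cohort.event, grp)
        rows.append(
            {
                "cohort": cohort.name,
                "covariate": "risk_group positive vs negative",
                "hr": fit.hr, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                "z": fit.z, "p": fit.p,
                "logrank_chi2": lr.chi_square, "logrank_p": lr.p,
                "n": fit.n, "n_events": fit.n_events,
            }
        )
        for label, mask in (("positive", grp), ("negative", ~grp)):
            km = km_estimate(cohort.time[mask], cohort.event[mask])
            q = run.outdir / f"km_{cohort.name}_{label}.tsv"
            km.to_frame().to_csv(q, sep="\t", index=False, float_format="%.10g")
            paths.append(q)
    p = run.outdir / "evaluation.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(p)
    return paths


def _stage_resample(run: _Run) -> list[Path]:
    cfg = run.config
    _require_simulated(run)
    if run.signature is None:
        sig_path = run.outdir / "signature.txt"
        if not sig_path.exists():
            raise DependencyError("'resample' stage requires a signature")
        run.signature = read_gene_list(sig_path)
    pool = [g for g in run.training.expression.index if g in run.validation.expression.index]
    result = prognostic_null_test(
        run.signature,
        run.training,
        run.validation,
        pool,
        n_resamples=cfg.n_resamples,
        seed=stage_seed(cfg.seed, "resample"),
        restandardize_per_cohort=cfg.restandardize_per_cohort,
    )
    p1 = run.outdir / "resampling_prognostic.json"
    p1.write_text(json.dumps(result.summary(), indent=2) + "\n")
    p2 = run.outdir / "resampling_prognostic_null.tsv"
    pd.Series(result.null_values, name="wald_z").to_csv(
        p2, sep="\t", index=False, float_format="%.10g"
    )
    return [p1, p2]


def _stage_network(run: _Run) -> list[Path]:
    cfg = run.config
    _require_simulated(run)
    if run.signature is None:
        sig_path = run.outdir / "signature.txt"
        if not sig_path.exists():
            raise DependencyError("'network' stage requires a signature")
        run.signature = read_gene_list(sig_path)
    # a subset of the signature keeps the per-resample forest cost desk-scale
    genes = run.signature[: cfg.coherence_genes]
    pool = [g for g in run.training.expression.index if g not in set(run.signature)]
    result = coherence_null_test(
        genes,
        run.training.expression,
        pool,
        n_resamples=cfg.coherence_resamples,
        seed=stage_seed(cfg.seed, "network"),
        n_trees=cfg.n_trees,
    )
    p = run.outdir / "coherence_test.json"
    p.write_text(json.dumps(result.summary(), indent=2) + "\n")
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "signature": _stage_signature,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "resample": _stage_resample,
    "network": _stage_network,
}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in order and write the run manifest.

    Returns the manifest dict (also written to ``<outdir>/run_manifest.json``).
    Any stage failure aborts with an error naming the stage.
    """
    run = _Run(config)
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        t0 = _time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](run)
        except DependencyError:
            raise
        except Exception as exc:
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
        extra = {}
        if stage == "signature":
            extra["n_selected"] = len(run.signature or [])
        if stage == "train" and run.model is not None:
            extra["n_model_genes"] = len(run.model.genes)
        run.record(stage, outputs, extra, elapsed=_time.perf_counter() - t0)
        logger.info("stage %s done (%d outputs)", stage, len(outputs))
    manifest_path = run.outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(run.manifest, indent=2, sort_keys=True) + "\n")
    return run.manifest


def report(manifest: dict[str, Any] | str | Path) -> str:
    """Human-readable summary of a finished run.

    Byte-identical for identical manifests; mirrors the evaluation layout:
    one row per cohort per covariate, then the resampling summaries.
    """
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    outdir = Path(manifest["config"]["outdir"])
    lines = [
        "vagsig run report",
        f"seed: {manifest['seed']}",
        "",
    ]
    stages = manifest.get("stages", {})
    if not stages:
        lines.append("warning: empty manifest (no stages were run)")
        return "\n".join(lines) + "\n"
    if "signature" in stages:
        lines.append(f"signature: {stages['signature'].get('n_selected', '?')} genes selected")
    eval_path = outdir / "evaluation.tsv"
    if eval_path.exists():
        df = pd.read_csv(eval_path, sep="\t")
        lines.append("")
        lines.append("survival evaluation (per cohort, per covariate):")
        for _, r in df.iterrows():
            lines.append(
                f"  {r['cohort']:<12} {r['covariate']:<36} "
                f"HR={r['hr']:.3g} ({r['ci_low']:.3g}, {r['ci_high']:.3g}) "
                f"p={r['p']:.3g}  log-rank p={r['logrank_p']:.3g}"
            )
    for name, label in (
        ("resampling_prognostic.json", "prognostic resampling test"),
        ("coherence_test.json", "co-expression coherence test"),
    ):
        path = outdir / name
        if path.exists():
            doc = json.loads(path.read_text())
            lines.append("")
            lines.append(
                f"{label}: observed={doc['observed']:.4g} "
                f"null median={doc['null_median']:.4g} "
                f"one-tailed p={doc['p_one_tailed']:.4g} "
                f"(n={doc['n_resamples']}, skipped={doc['n_skipped']})"
            )
    km_files = sorted(p.name for p in outdir.glob("km_*.tsv"))
    if km_files:
        lines.append("")
        lines.append("KM curve files: " + ", ".join(km_files))
    return "\n".join(lines) + "\n"
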