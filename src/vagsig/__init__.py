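"""vagsig: multi-cancer prognostic gene-signature analysis.

Derive a cross-cancer differential-expression signature from paired
normal/tumor cohorts, build a Wald-weighted standardized risk score, evaluate
recurrence-free-survival separation in independent cohorts, and test both
prognostic power and co-expression coherence against random same-size gene
signatures.
"""

from importlib import resources

__version__ = "0.1.0"

from .containers import (  # noqa: F401
    CoxFit,
    KMCurve,
    LogRankResult,
    PairedCohort,
    ResamplingResult,
    RiskAssignment,
    ScoringModel,
    SurvivalCohort,
)
from .de import (  # noqa: F401
    SelectionRule,
    bh_adjust,
    complement_pool,
    de_test_cohort,
    de_test_cohorts,
    fold_change,
    paired_t_test,
    select_common_de,
    term_enrichment,
)
from .io import (  # noqa: F401
    collapse_probes,
    detection_filter,
    drop_sex_chromosomes,
    read_clinical,
    read_expression,
    read_gene_list,
    read_scoring_model,
    write_clinical,
    write_expression,
    write_gene_list,
    write_scoring_model,
)
from .network import coherence_statistic, infer_adjacency  # noqa: F401
from .pipeline import RunConfig, report, run_pipeline  # noqa: F401
from .resampling import (  # noqa: F401
    coherence_null_test,
    pooled_sum_z_test,
    prognostic_null_test,
    random_signatures,
    signature_wald_z,
)
from .scoring import (  # noqa: F401
    build_scoring_model,
    compute_risk_scores,
    dichotomize,
    fit_univariate_cox,
)
from .simulate import (  # noqa: F401
    PairedSimConfig,
    SurvSimConfig,
    generate_paired_cohorts,
    generate_survival_cohort,
)
from .survival import (  # noqa: F401
    cox_multivariate,
    km_estimate,
    logrank_test,
    stratified_vag_analysis,
)


def vag_signature() -> list[str]:
    """The 45-gene VDAC1-associated gene signature shipped with the package."""
    from .io import read_gene_list

    with resources.as_file(
        resources.files("vagsig").joinpath("data/vag_signature.txt")
    ) as path:
        return read_gene_list(path)
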