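"""Simulate paired normal/tumor cohorts and a survival cohort.

Builds six small paired cohorts with 20 planted differentially expressed
genes and one survival cohort whose hazard depends on 5 of those genes,
then prints what the ground truth looks like.
"""

from vagsig import (
    PairedSimConfig,
    SurvSimConfig,
    generate_paired_cohorts,
    generate_survival_cohort,
)

planted = {f"G{i:04d}": 1.0 for i in range(1, 21)}  # +1.0 log2 in tumors
cohorts, truth = generate_paired_cohorts(
    PairedSimConfig(
        n_cancers=6, n_genes=200, n_patients_per_cancer=25,
        de_genes=planted, accordant_in=5, seed=1,
    )
)
print(f"{len(cohorts)} paired cohorts of {cohorts[0].n_pairs} patients, "
      f"{cohorts[0].expression.shape[0]} genes each")
print("ground truth (first rows):")
print(truth.head(4).to_string(index=False))
# each row records one (gene, cancer) perturbation the DE stage should find

cohort, beta = generate_survival_cohort(
    SurvSimConfig(
        n_samples=200, n_genes=200,
        signature_genes=tuple(planted), betas={g: 0.4 for g in list(planted)[:5]},
        latent_factor_loading=0.5, seed=2,
    )
)
print(f"\nsurvival cohort: {cohort.n_samples} samples, "
      f"{int(cohort.event.sum())} recurrence events, "
      f"{(beta != 0).sum()} genes with true log-hazard effects")
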