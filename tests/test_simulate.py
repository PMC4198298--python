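"""Generator ground truth, determinism, and calibration of downstream tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vagsig import (
    PairedSimConfig,
    SelectionRule,
    SurvSimConfig,
    de_test_cohorts,
    generate_paired_cohorts,
    generate_survival_cohort,
    select_common_de,
)
from vagsig.cox import cox_fit_many
from vagsig.errors import ConfigurationError
from vagsig.survival import logrank_test


class TestPairedSimulator:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            PairedSimConfig(n_cancers=0)
        with pytest.raises(ConfigurationError):
            PairedSimConfig(noise_sd=0.0)
        with pytest.raises(ConfigurationError):
            PairedSimConfig(n_cancers=3, accordant_in=4, de_genes={"G0001": 1.0})
        with pytest.raises(ConfigurationError):
            PairedSimConfig(n_genes=2, de_genes={"G0001": 1.0, "G0002": 1.0, "G0003": 1.0})

    def test_seeded_determinism_bitwise(self):
        cfg = PairedSimConfig(n_cancers=2, n_genes=50, n_patients_per_cancer=10,
                              de_genes={"G0003": 1.0}, accordant_in=2, seed=7)
        a, truth_a = generate_paired_cohorts(cfg)
        b, truth_b = generate_paired_cohorts(cfg)
        for ca, cb in zip(a, b):
            assert ca.expression.to_numpy().tobytes() == cb.expression.to_numpy().tobytes()
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_planted_effect_recovered_within_3se(self):
        # effect +1.0 log2 in 5 of 6 cancers; diff variance = 2 * noise_sd^2
        cfg = PairedSimConfig(
            n_cancers=6, n_genes=200, n_patients_per_cancer=30,
            de_genes={"G0001": 1.0}, accordant_in=5, noise_sd=0.5, seed=11,
        )
        cohorts, truth = generate_paired_cohorts(cfg)
        perturbed = set(truth.loc[truth["gene"] == "G0001", "cancer"])
        assert len(perturbed) == 5
        se = np.sqrt(2 * 0.5**2 / 30)
        for cohort in cohorts:
            mean_diff = cohort.differences().loc["G0001"].mean()
            target = 1.0 if cohort.cancer in perturbed else 0.0
            assert abs(mean_diff - target) < 3 * se

    def test_null_model_selects_nothing_beyond_fdr(self):
        cfg = PairedSimConfig(n_cancers=6, n_genes=400, n_patients_per_cancer=20,
                              de_genes={}, seed=3)
        cohorts, _ = generate_paired_cohorts(cfg)
        selected = select_common_de(de_test_cohorts(cohorts), SelectionRule())
        # no gene is truly DE: requiring BH < 0.05 in >= 4 cancers is
        # essentially impossible under the null
        assert len(selected) == 0

    def test_explicit_per_cancer_effects(self):
        cfg = PairedSimConfig(
            n_cancers=4, n_genes=10, n_patients_per_cancer=25,
            de_genes={"G0001": {"cancer1": 2.0, "cancer2": -2.0}}, seed=5,
        )
        cohorts, truth = generate_paired_cohorts(cfg)
        assert set(truth["direction"]) == {"up", "down"}
        by_cancer = {c.cancer: c for c in cohorts}
        assert by_cancer["cancer1"].differences().loc["G0001"].mean() > 1
        assert by_cancer["cancer2"].differences().loc["G0001"].mean() < -1


class TestSurvivalSimulator:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SurvSimConfig(latent_factor_loading=1.0)
        with pytest.raises(ConfigurationError):
            SurvSimConfig(baseline_hazard=0.0)
        with pytest.raises(ConfigurationError):
            SurvSimConfig(signature_genes=("G0001",), betas={"G0099": 1.0})

    def test_seeded_determinism_bitwise(self):
        cfg = SurvSimConfig(n_samples=50, n_genes=20, seed=9)
        a, _ = generate_survival_cohort(cfg)
        b, _ = generate_survival_cohort(cfg)
        assert a.expression.to_numpy().tobytes() == b.expression.to_numpy().tobytes()
        assert a.clinical.to_numpy().tobytes() == b.clinical.to_numpy().tobytes()

    def test_null_wald_statistics_standard_normal(self):
        cfg = SurvSimConfig(n_samples=250, n_genes=300, seed=21,
                            baseline_hazard=0.05, censoring_rate=0.02)
        cohort, _ = generate_survival_cohort(cfg)
        res = cox_fit_many(cohort.expression.to_numpy().T, cohort.time, cohort.event)
        z = res["z"]
        assert abs(np.mean(z)) < 3 / np.sqrt(len(z))
        assert 0.8 < np.std(z) < 1.2

    def test_single_gene_beta_recovered(self):
        cfg = SurvSimConfig(
            n_samples=1000, n_genes=5, signature_genes=("G0001",),
            betas={"G0001": 0.5}, seed=13, baseline_hazard=0.05,
            censoring_rate=0.02,
        )
        cohort, beta = generate_survival_cohort(cfg)
        assert beta["G0001"] == 0.5
        res = cox_fit_many(
            cohort.expression.loc["G0001"].to_numpy(), cohort.time, cohort.event
        )
        assert abs(res["beta"][0] - 0.5) < 0.15

    def test_latent_factor_raises_signature_correlation(self):
        sig = tuple(f"G{i:04d}" for i in range(1, 11))
        cfg = SurvSimConfig(n_samples=400, n_genes=40, signature_genes=sig,
                            latent_factor_loading=0.9, seed=17)
        cohort, _ = generate_survival_cohort(cfg)
        corr = np.corrcoef(cohort.expression.to_numpy())
        idx = np.arange(10)
        off = ~np.eye(10, dtype=bool)
        sig_corr = corr[np.ix_(idx, idx)][off].mean()
        rest = np.arange(10, 40)
        off_rest = ~np.eye(30, dtype=bool)
        rest_corr = corr[np.ix_(rest, rest)][off_rest].mean()
        assert sig_corr > 0.5 > abs(rest_corr) + 0.3
        # factor-model algebra: pairwise correlation ~ loading^2
        assert abs(sig_corr - 0.81) < 0.1

    def test_censoring_fraction_monotone_in_rate(self):
        fractions = []
        for rate in (0.0, 0.01, 0.05, 0.2, 1.0):
            cfg = SurvSimConfig(n_samples=300, n_genes=5, censoring_rate=rate,
                                baseline_hazard=0.05, seed=31)
            cohort, _ = generate_survival_cohort(cfg)
            fractions.append(1.0 - cohort.event.mean())
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[0] < fractions[-1]

    def test_logrank_p_uniform_under_null(self):
        """Dichotomizing unrelated expression yields uniform log-rank P."""
        pvals = []
        for seed in range(200):
            cfg = SurvSimConfig(n_samples=60, n_genes=2, seed=seed,
                                baseline_hazard=0.05, censoring_rate=0.02)
            cohort, _ = generate_survival_cohort(cfg)
            x = cohort.expression.loc["G0001"].to_numpy()
            grp = x > np.median(x)
            pvals.append(logrank_test(cohort.time, cohort.event, grp).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
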