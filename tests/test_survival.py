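"""Kaplan-Meier, log-rank, multivariate Cox, and stratified analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vagsig import (
    cox_multivariate,
    fit_univariate_cox,
    km_estimate,
    logrank_test,
    stratified_vag_analysis,
)
from vagsig.cox import cox_fit_many
from vagsig.errors import (
    DegenerateDesignError,
    ValidationError,
)

from conftest import make_survival_cohort


class TestKMEstimate:
    def test_three_events_by_hand(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_all_censored_flat_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.times.size == 0  # no steps: S(t) = 1 throughout

    def test_censoring_reduces_at_risk_without_step(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.times.tolist() == [1.0, 3.0]
        # after the censored sample drops out only 1 is at risk at t=3
        assert km.at_risk.tolist() == [3, 1]
        assert km.survival == pytest.approx([2 / 3, 0.0])

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = rng.exponential(5, 40) + 0.01
        km = km_estimate(times, np.ones(40, dtype=int))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestLogRank:
    def test_hand_computed_four_samples(self):
        # times (1,2,3,4), all events, groups (A,A,B,B):
        # O_A = 2, E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36
        # chi2 = (2 - 5/6)^2 / (17/36) = 2.882353
        res = logrank_test([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], [0, 0, 1, 1])
        assert res.chi_square == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-6)
        assert res.df == 1
        assert res.p == pytest.approx(
            stats.chi2.sf(res.chi_square, 1), abs=1e-12
        )

    def test_symmetry_under_label_swap(self, small_survival_cohort):
        c = small_survival_cohort
        grp = c.expression.loc["G0001"].to_numpy() > 8.0
        a = logrank_test(c.time, c.event, grp)
        b = logrank_test(c.time, c.event, ~grp)
        assert a.chi_square == pytest.approx(b.chi_square, rel=1e-12)

    def test_single_group_rejected(self, small_survival_cohort):
        c = small_survival_cohort
        with pytest.raises(ValidationError):
            logrank_test(c.time, c.event, np.zeros(c.n_samples, dtype=bool))

    def test_equals_cox_score_test_on_untied_data(self, small_survival_cohort):
        from vagsig.cox import cox_score_chi2

        c = small_survival_cohort
        assert np.unique(c.time).size == c.n_samples  # untied
        grp = (c.expression.loc["G0002"].to_numpy() > 8.0).astype(float)
        lr = logrank_test(c.time, c.event, grp.astype(bool))
        assert cox_score_chi2(grp, c.time, c.event) == pytest.approx(
            lr.chi_square, abs=1e-6
        )


class TestCoxMultivariate:
    def test_single_binary_covariate_matches_univariate(self, small_survival_cohort):
        c = small_survival_cohort
        clin = c.clinical.copy()
        clin["grp"] = (c.expression.loc["G0001"].to_numpy() > 8.0).astype(float)
        table = cox_multivariate(clin, ["grp"])
        uni = fit_univariate_cox(clin["grp"], clin)
        assert table.loc[0, "hr"] == pytest.approx(uni.hr, rel=1e-3)
        assert table.loc[0, "p"] == pytest.approx(uni.p, rel=1e-2, abs=1e-12)

    def test_two_planted_effects_recovered(self):
        rng = np.random.default_rng(5)
        n = 1000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x1 - 0.5 * x2)) + 1e-6
        clin = pd.DataFrame(
            {"time": t, "event": 1, "x1": x1, "x2": x2},
            index=[f"s{i}" for i in range(n)],
        )
        table = cox_multivariate(clin, ["x1", "x2"]).set_index("covariate")
        assert np.log(table.loc["x1", "hr"]) == pytest.approx(0.5, abs=0.2)
        assert np.log(table.loc["x2", "hr"]) == pytest.approx(-0.5, abs=0.2)

    def test_duplicated_covariate_degenerate(self, small_survival_cohort):
        clin = small_survival_cohort.clinical.copy()
        clin["a"] = np.arange(len(clin), dtype=float)
        clin["b"] = clin["a"]
        with pytest.raises(DegenerateDesignError, match="b"):
            cox_multivariate(clin, ["a", "b"])

    def test_categorical_needs_declared_reference(self, small_survival_cohort):
        clin = small_survival_cohort.clinical.copy()
        clin["stage"] = np.where(np.arange(len(clin)) % 2 == 0, "I", "III")
        with pytest.raises(ValidationError, match="reference"):
            cox_multivariate(clin, ["stage"])
        table = cox_multivariate(clin, ["stage"], categorical={"stage": "I"})
        assert table.loc[0, "covariate"] == "stage[III vs I]"

    def test_wald_p_uniform_under_null(self, small_survival_cohort):
        """Type-I calibration: 500 independent null binary covariates."""
        c = small_survival_cohort
        rng = np.random.default_rng(99)
        X = (rng.random((c.n_samples, 500)) < 0.5).astype(float)
        res = cox_fit_many(X, c.time, c.event)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


class TestStratified:
    def test_constant_stratum_equals_whole_cohort(self, small_survival_cohort):
        c = small_survival_cohort
        clin = c.clinical.copy()
        clin["stratum"] = "all"
        positive = pd.Series(
            c.expression.loc["G0001"].to_numpy() > 8.0, index=clin.index
        )
        res = stratified_vag_analysis(clin, positive, "stratum")
        assert list(res) == ["all"]
        direct = fit_univariate_cox(positive.astype(float), clin)
        assert res["all"].fit.hr == pytest.approx(direct.hr, rel=1e-9)

    def test_planted_stratum_specific_hazard_ordering(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frames = []
            for stratum, loghr in (("s1", np.log(2.0)), ("s2", 0.0)):
                n = 300
                grp = (rng.random(n) < 0.5).astype(float)
                t = rng.exponential(1 / (0.1 * np.exp(loghr * grp))) + 1e-6
                frames.append(
                    pd.DataFrame(
                        {
                            "time": np.minimum(t, 60.0),
                            "event": (t <= 60.0).astype(int),
                            "stratum": stratum,
                            "grp": grp,
                        },
                        index=[f"{stratum}_{i}" for i in range(n)],
                    )
                )
            clin = pd.concat(frames)
            positive = clin["grp"].astype(bool)
            res = stratified_vag_analysis(clin, positive, "stratum")
            hits += res["s1"].fit.hr > res["s2"].fit.hr
        assert hits >= 19

    def test_stratum_without_events_skipped(self, small_survival_cohort):
        c = small_survival_cohort
        clin = c.clinical.copy()
        clin["stratum"] = np.where(np.arange(len(clin)) < 20, "dead_zone", "rest")
        clin.loc[clin["stratum"] == "dead_zone", "event"] = 0
        positive = pd.Series(
            c.expression.loc["G0002"].to_numpy() > 8.0, index=clin.index
        )
        res = stratified_vag_analysis(clin, positive, "stratum")
        assert "dead_zone" not in res
        assert "rest" in res
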