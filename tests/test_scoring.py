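"""Univariate Cox fits, scoring-model construction, risk scores, dichotomy."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from vagsig import (
    ScoringModel,
    SurvivalCohort,
    build_scoring_model,
    compute_risk_scores,
    dichotomize,
    fit_univariate_cox,
)
from vagsig.errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

from conftest import make_survival_cohort


class TestFitUnivariateCox:
    def test_matches_lifelines(self, small_survival_cohort):
        cohort = small_survival_cohort
        x = cohort.expression.loc["G0001"]
        fit = fit_univariate_cox(x, cohort.clinical)
        frame = pd.DataFrame(
            {"x": x.to_numpy(), "time": cohort.time, "event": cohort.event}
        )
        ref = CoxPHFitter().fit(frame, "time", "event")
        # lifelines' own convergence criterion leaves ~1e-4 slack
        assert fit.beta == pytest.approx(ref.params_.iloc[0], abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_.iloc[0], abs=1e-4)
        assert fit.hr == pytest.approx(np.exp(fit.beta))
        assert fit.ci_low < fit.hr < fit.ci_high

    def test_matches_lifelines_with_ties(self, small_survival_cohort):
        cohort = small_survival_cohort
        clin = cohort.clinical.copy()
        clin["time"] = np.ceil(clin["time"])  # force heavy ties
        x = cohort.expression.loc["G0002"]
        fit = fit_univariate_cox(x, clin)
        frame = pd.DataFrame({"x": x.to_numpy(), "time": clin["time"].to_numpy(),
                              "event": clin["event"].to_numpy()})
        ref = CoxPHFitter().fit(frame, "time", "event")
        assert fit.beta == pytest.approx(ref.params_.iloc[0], abs=1e-4)
        assert fit.se == pytest.approx(ref.standard_errors_.iloc[0], abs=1e-4)

    def test_rescaling_invariance(self, small_survival_cohort):
        """x -> 2x halves beta and leaves the Wald z unchanged."""
        cohort = small_survival_cohort
        x = cohort.expression.loc["G0003"].to_numpy()
        a = fit_univariate_cox(x, cohort.clinical)
        b = fit_univariate_cox(2 * x, cohort.clinical)
        assert b.beta == pytest.approx(a.beta / 2, rel=1e-6)
        assert b.z == pytest.approx(a.z, rel=1e-6)

    def test_zero_variance_rejected(self, small_survival_cohort):
        with pytest.raises(DegenerateDataError):
            fit_univariate_cox(
                np.ones(small_survival_cohort.n_samples),
                small_survival_cohort.clinical,
            )

    def test_too_few_events_rejected(self, small_survival_cohort):
        clin = small_survival_cohort.clinical.copy()
        clin["event"] = 0
        with pytest.raises(InsufficientDataError):
            fit_univariate_cox(
                small_survival_cohort.expression.loc["G0001"], clin
            )

    def test_null_calibration(self):
        """Unrelated covariates rarely reach |z| > 3."""
        extreme = 0
        for seed in range(200):
            cohort = make_survival_cohort(n=150, seed=seed + 1000)
            fit = fit_univariate_cox(
                cohort.expression.loc["G0010"], cohort.clinical
            )
            extreme += abs(fit.z) > 3
        assert extreme <= 2  # >= 99% within +-3


class TestBuildScoringModel:
    def test_single_gene_model(self, small_survival_cohort):
        model = build_scoring_model(small_survival_cohort, ["G0001"])
        assert model.genes == ["G0001"]
        row = model.weights.loc["G0001"]
        x = small_survival_cohort.expression.loc["G0001"]
        assert row["mu"] == pytest.approx(x.mean())
        assert row["tau"] == pytest.approx(x.std(ddof=1))

    def test_constant_gene_dropped(self, small_survival_cohort):
        cohort = small_survival_cohort
        expr = cohort.expression.copy()
        expr.loc["G0001"] = 5.0
        cohort2 = SurvivalCohort("c", expr, cohort.clinical.copy())
        model = build_scoring_model(cohort2, ["G0001", "G0002"])
        assert model.genes == ["G0002"]

    def test_mostly_missing_signature_rejected(self, small_survival_cohort):
        with pytest.raises(InsufficientDataError):
            build_scoring_model(
                small_survival_cohort, ["G0001", "nope1", "nope2", "nope3"]
            )

    def test_weights_are_wald_statistics(self, small_survival_cohort):
        model = build_scoring_model(small_survival_cohort, ["G0004"])
        fit = fit_univariate_cox(
            small_survival_cohort.expression.loc["G0004"],
            small_survival_cohort.clinical,
        )
        assert model.weights.loc["G0004", "z"] == pytest.approx(fit.z, abs=1e-8)


def _model_from_arrays(genes, z, mu, tau):
    return ScoringModel(
        weights=pd.DataFrame({"z": z, "mu": mu, "tau": tau},
                             index=pd.Index(genes, name="gene")),
        training_cohort="t",
    )


def _cohort_from_values(genes, values):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    expr = pd.DataFrame(values, index=genes,
                        columns=[f"s{i}" for i in range(n)])
    rng = np.random.default_rng(0)
    clinical = pd.DataFrame(
        {"time": rng.exponential(10, n) + 0.1, "event": 1},
        index=expr.columns,
    )
    return SurvivalCohort("v", expr, clinical)


class TestComputeRiskScores:
    def test_formula_single_gene(self):
        model = _model_from_arrays(["g"], [2.0], [5.0], [1.0])
        cohort = _cohort_from_values(["g"], [[6.0, 5.0, 4.0]])
        ra = compute_risk_scores(model, cohort)
        assert ra.scores.to_numpy() == pytest.approx([2.0, 0.0, -2.0])

    def test_three_gene_weighted_sum(self):
        model = _model_from_arrays(["a", "b", "c"], [1.0, -2.0, 0.5],
                                   [0.0, 0.0, 0.0], [1.0, 2.0, 4.0])
        cohort = _cohort_from_values(["a", "b", "c"],
                                     [[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        ra = compute_risk_scores(model, cohort)
        assert ra.scores.iloc[0] == pytest.approx(1 - 1 + 0.125)
        assert ra.scores.iloc[1] == pytest.approx(0.0)

    def test_all_zero_weights_give_zero_scores(self):
        model = _model_from_arrays(["a", "b"], [0.0, 0.0], [1.0, 2.0], [1.0, 1.0])
        cohort = _cohort_from_values(["a", "b"], np.random.default_rng(1).normal(size=(2, 5)))
        ra = compute_risk_scores(model, cohort)
        assert np.all(ra.scores.to_numpy() == 0.0)

    def test_gene_order_invariance(self, small_survival_cohort):
        genes = ["G0001", "G0002", "G0005"]
        model = build_scoring_model(small_survival_cohort, genes)
        reordered = ScoringModel(
            weights=model.weights.iloc[::-1], training_cohort="t"
        )
        a = compute_risk_scores(model, small_survival_cohort)
        b = compute_risk_scores(reordered, small_survival_cohort)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-12)

    def test_missing_genes_dropped_from_sum(self):
        model = _model_from_arrays(["a", "b"], [1.0, 5.0], [0.0, 0.0], [1.0, 1.0])
        cohort = _cohort_from_values(["a"], [[1.0, 2.0, 3.0]])
        ra = compute_risk_scores(model, cohort)
        assert ra.n_genes_used == 1
        assert ra.n_genes_missing == 1
        assert ra.scores.to_numpy() == pytest.approx([1.0, 2.0, 3.0])

    def test_no_genes_present_rejected(self):
        model = _model_from_arrays(["a"], [1.0], [0.0], [1.0])
        cohort = _cohort_from_values(["x"], [[1.0, 2.0]])
        with pytest.raises(ValidationError):
            compute_risk_scores(model, cohort)

    def test_restandardize_uses_cohort_moments(self):
        model = _model_from_arrays(["a"], [1.0], [100.0], [50.0])
        values = np.array([[1.0, 2.0, 3.0, 4.0]])
        cohort = _cohort_from_values(["a"], values)
        ra = compute_risk_scores(model, cohort, restandardize_per_cohort=True)
        x = values[0]
        expected = (x - x.mean()) / x.std(ddof=1)
        assert ra.scores.to_numpy() == pytest.approx(expected)


class TestDichotomize:
    def test_even_split(self):
        positive, median = dichotomize(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert median == 2.5
        assert positive.tolist() == [False, False, True, True]

    def test_tie_at_median_goes_negative(self):
        positive, median = dichotomize(pd.Series([1.0, 2.0, 3.0]))
        assert median == 2.0
        assert positive.tolist() == [False, False, True]

    def test_all_equal_warns_all_negative(self):
        with pytest.warns(UserWarning, match="equal"):
            positive, _ = dichotomize(pd.Series([1.0, 1.0, 1.0]))
        assert not positive.any()

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize(pd.Series([1.0]))
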