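"""Scheffe mixture regression: design matrix, ANOVA, pruning, prediction."""

import numpy as np
import pytest

from statediagrams import (
    ALL_TERMS,
    LINEAR_TERMS,
    ChenParams,
    Composition,
    DomainError,
    MixtureDesign,
    chen_tm,
    design_matrix,
    fit_mixture_model,
    predict_response,
    predict_state_diagram,
    prune_model,
)

EXP5_BASE = Composition(0.283, 0.283, 0.283, 0.075, 0.075, 0.0, sum_tol=2e-3)


class TestDesignMatrix:
    def test_vertex_run(self, design):
        x = design_matrix(design, ["XF", "XG", "XFXG"])
        assert x[0].tolist() == [1.0, 0.0, 0.0]  # pure fructose

    def test_interaction_is_elementwise_product(self, design):
        x = design_matrix(design, ["XFXP"])
        assert x[4, 0] == pytest.approx(0.283 * 0.075)  # exp 5

    def test_zero_component_zeroes_interaction(self, design):
        x = design_matrix(design, ["XGXM"])
        xm = design.component_matrix()[:, 5]
        assert np.all(x[xm == 0.0, 0] == 0.0)

    def test_unknown_term_rejected(self, design):
        with pytest.raises(ValueError, match="unknown term"):
            design_matrix(design, ["XFXFXF"])


class TestFitMixtureModel:
    def test_refit_of_published_tm_prime_model(self, fixtures):
        """The 11-term refit on the published design and responses lands on
        the published coefficients and ANOVA."""
        y = fixtures.table2["tm_prime"].to_numpy(dtype=float)
        terms = fixtures.table3["tm_prime"].terms
        model = fit_mixture_model(fixtures.table1, y, terms, "tm_prime")
        assert model.coef("XF") == pytest.approx(-42.92, abs=0.5)
        assert model.anova.r_squared == pytest.approx(0.994, abs=0.005)
        assert model.anova.cv_percent == pytest.approx(2.02, abs=0.1)

    def test_noiseless_interpolation_recovers_coefficients(self, design):
        rng = np.random.default_rng(7)
        terms = list(LINEAR_TERMS) + ["XFXM", "XPXM"]
        truth = rng.normal(0.0, 10.0, len(terms))
        y = design_matrix(design, terms) @ truth
        model = fit_mixture_model(design, y, terms)
        assert np.allclose(model.coefficients, truth, atol=1e-8)
        assert model.anova.r_squared == pytest.approx(1.0, abs=1e-9)
        assert model.anova.sd == pytest.approx(0.0, abs=1e-8)

    def test_underdetermined_rejected(self, design):
        small = MixtureDesign(runs=design.runs[:5])
        with pytest.raises(ValueError, match="underdetermined"):
            fit_mixture_model(small, np.zeros(5), LINEAR_TERMS)

    def test_rank_deficiency_names_terms(self, design):
        # replicate one run 25 times -> every column collinear
        degenerate = MixtureDesign(runs=(design.runs[0],) * 25)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mixture_model(degenerate, np.zeros(25), LINEAR_TERMS)

    def test_zero_variance_responses_rejected(self, design):
        with pytest.raises(ValueError, match="variance"):
            fit_mixture_model(design, np.ones(25), LINEAR_TERMS)


class TestPruning:
    def test_linear_generator_prunes_to_equivalent_model(self, design):
        """Responses from a linear-only blend: elimination sometimes removes
        every interaction, and whatever spurious interactions survive (the
        design's interaction columns are heavily collinear with the linear
        ones, so their t-tests are correlated) cancel against shifted linear
        coefficients -- the pruned model's predictions stay within a few
        noise SDs of the generating surface at every design point."""
        truth = np.array([8.0, 30.0, 59.0, 12.0, -8.0, 10.0])
        x = design_matrix(design, LINEAR_TERMS)
        surface = x @ truth
        fully = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = surface + rng.normal(0.0, 0.05, 25)
            model = prune_model(design, y)
            if set(model.terms) == set(LINEAR_TERMS):
                fully += 1
            xp = design_matrix(design, model.terms)
            pred = xp @ np.array(model.coefficients)
            assert np.abs(pred - surface).max() < 0.25  # 5 noise SDs
        assert fully >= 2  # simulation oracle: 4/20 at this seed set

    def test_strong_interaction_retained(self, design):
        """A dominant pairwise blend survives elimination in >= 18 of 20
        seeded replicates (simulation oracle: 19/20)."""
        truth_terms = list(LINEAR_TERMS) + ["XPXM"]
        truth = np.array([8.0, 30.0, 59.0, 12.0, -8.0, 10.0, 400.0])
        x = design_matrix(design, truth_terms)
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = x @ truth + rng.normal(0.0, 0.05, 25)
            model = prune_model(design, y)
            kept += "XPXM" in model.terms
        assert kept >= 18

    def test_alpha_one_keeps_full_model(self, design):
        rng = np.random.default_rng(3)
        y = rng.normal(-35.0, 5.0, 25)
        model = prune_model(design, y, alpha=1.0)
        assert model.terms == ALL_TERMS

    def test_residual_df_never_below_linear_model(self, design):
        rng = np.random.default_rng(11)
        y = rng.normal(-35.0, 5.0, 25)
        model = prune_model(design, y, alpha=0.10)
        assert len(model.terms) >= len(LINEAR_TERMS)
        assert all(t in model.terms for t in LINEAR_TERMS)


class TestPredictResponse:
    def test_vertex_prediction_equals_linear_coefficient(self, models):
        fructose = Composition(1, 0, 0, 0, 0, 0)
        sucrose = Composition(0, 0, 1, 0, 0, 0)
        assert predict_response(models["tm_prime"], fructose) == pytest.approx(-42.92)
        assert predict_response(models["tgs"], sucrose) == pytest.approx(58.68)

    def test_matches_design_matrix_evaluation(self, design, models):
        model = models["k"]
        x = design_matrix(design, model.terms)
        expected = x @ np.array(model.coefficients)
        got = [predict_response(model, comp) for _, comp in design.runs]
        assert np.allclose(got, expected, atol=1e-12)


class TestPredictStateDiagram:
    def test_base_prediction_near_measured_value(self, fixtures):
        """At XM=0 the predicted Tm' for the five-solute base should sit
        within a couple of model SDs of the measured -38.7 degC."""
        diagram = predict_state_diagram(EXP5_BASE, 0.0, fixtures.table3)
        sd = fixtures.table3["tm_prime"].anova.sd
        assert diagram.mfcc.tm_prime == pytest.approx(-38.7, abs=2 * sd)

    def test_maltodextrin_sweep_raises_tm_prime(self, models):
        sweep = np.linspace(0.0, 0.6, 13)
        tm_primes = [
            predict_state_diagram(EXP5_BASE, xm, models).mfcc.tm_prime
            for xm in sweep
        ]
        assert np.all(np.diff(tm_primes) > 0.0)

    def test_freezing_curve_flattens_with_maltodextrin(self, models):
        lo = predict_state_diagram(EXP5_BASE, 0.3, models)
        hi = predict_state_diagram(EXP5_BASE, 0.6, models)
        # less depression at mid-concentration when more polymer is present
        assert chen_tm(0.5, hi.chen) > chen_tm(0.5, lo.chen)

    def test_base_ratios_preserved(self, models):
        diagram = predict_state_diagram(EXP5_BASE, 0.4, models)
        comp = diagram.composition
        assert comp.xm == 0.4
        assert comp.xf / comp.xp == pytest.approx(0.283 / 0.075)

    def test_invalid_inputs_rejected(self, models):
        with pytest.raises(DomainError):
            predict_state_diagram(EXP5_BASE, 1.0, models)
        with pytest.raises(ValueError, match="maltodextrin"):
            nonzero_xm = Composition(0.3, 0.3, 0.2, 0.0, 0.0, 0.2)
            predict_state_diagram(nonzero_xm, 0.2, models)

    def test_missing_model_rejected(self, models):
        partial = {k: v for k, v in models.items() if k != "b"}
        with pytest.raises(ValueError, match="missing"):
            predict_state_diagram(EXP5_BASE, 0.2, partial)
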