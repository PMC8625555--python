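"""Mixed-model fitting, bridge regression, composition and validation."""

import numpy as np
import pytest

from glyload import (
    GLBridgeCoefficients,
    GlycemicRecord,
    MealNutrients,
    MealSummary,
    PUBLISHED_IAUC_COEFFICIENTS,
    SimulationConfig,
    compose_gl_formula,
    compute_records,
    fit_gl_bridge,
    fit_iauc_mixed_model,
    simulate_study,
    validate_predictions,
)
from glyload.errors import (
    DegenerateRegressionError,
    InsufficientDataError,
    JoinError,
    SingularDesignError,
)
from glyload.models import DEFAULT_IAUC_SCALE
from glyload.predict import predict_gl


def _meal(meal_id, carb, fiber, protein, fat, tier=50):
    return MealNutrients(meal_id, meal_id, 300, carb, fiber, protein, fat, tier)


def _noiseless_records(meals, coeffs, participants=("P1", "P2", "P3")):
    recs = []
    for pid in participants:
        for m in meals:
            iauc = DEFAULT_IAUC_SCALE * coeffs.linear_predictor(m)
            recs.append(GlycemicRecord(pid, m.meal_id, iauc, 4000.0, 50.0, 20.0))
    return recs


VARIED_MEALS = [
    _meal("a", 25, 1, 4, 2),
    _meal("b", 50, 5, 10, 8),
    _meal("c", 75, 2, 20, 15),
    _meal("d", 40, 8, 6, 20),
    _meal("e", 60, 3, 15, 5),
    _meal("f", 30, 0, 2, 12),
]


class TestMixedModel:
    def test_noiseless_recovery_to_six_significant_digits(self):
        recs = _noiseless_records(VARIED_MEALS, PUBLISHED_IAUC_COEFFICIENTS)
        fit = fit_iauc_mixed_model(recs, VARIED_MEALS)
        for name, truth in PUBLISHED_IAUC_COEFFICIENTS.betas.items():
            assert fit.betas[name] == pytest.approx(truth, rel=1e-6)

    def test_single_participant_falls_back_to_ols(self, caplog):
        recs = _noiseless_records(
            VARIED_MEALS, PUBLISHED_IAUC_COEFFICIENTS, participants=("P1",)
        )
        with caplog.at_level("WARNING", logger="glyload.models"):
            fit = fit_iauc_mixed_model(recs, VARIED_MEALS)
        assert fit.ols_fallback
        assert fit.betas["available_carb"] == pytest.approx(0.35, rel=1e-6)

    def test_rank_deficient_design_rejected(self):
        # all meals share one composition: columns are collinear
        meals = [_meal(str(i), 50, 5, 10, 8) for i in range(4)]
        recs = _noiseless_records(meals, PUBLISHED_IAUC_COEFFICIENTS)
        with pytest.raises(SingularDesignError):
            fit_iauc_mixed_model(recs, meals)

    def test_unknown_meal_id_is_a_join_error(self):
        rec = GlycemicRecord("P1", "ghost", 2000.0, 4000.0, 50.0, 20.0)
        with pytest.raises(JoinError):
            fit_iauc_mixed_model([rec], VARIED_MEALS)

    def test_stochastic_recovery_of_carbohydrate_effect(self):
        """Across replicate simulated studies, each fixed effect's mean lands
        within 2 Monte-Carlo standard errors of its generating value."""
        estimates = {k: [] for k in PUBLISHED_IAUC_COEFFICIENTS.betas}
        for seed in range(1, 11):
            study = simulate_study(SimulationConfig(seed=seed))
            recs = compute_records(study.curves, study.meals)
            fit = fit_iauc_mixed_model(recs, study.meals)
            assert not fit.ols_fallback
            for k in estimates:
                estimates[k].append(fit.betas[k])
        for name, truth in PUBLISHED_IAUC_COEFFICIENTS.betas.items():
            vals = np.asarray(estimates[name])
            mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - truth) <= 2 * mc_se + 1e-12, name

    def test_wald_pvalues_reported_for_all_effects(self, default_records, default_study):
        fit = fit_iauc_mixed_model(default_records, default_study.meals)
        assert set(fit.p_values) == {
            "intercept", "available_carb", "fat", "protein_sq", "fiber_sq",
        }
        assert fit.p_values["available_carb"] < 1e-6
        assert fit.participant_variance > 0

    def test_permutation_invariance(self, default_records, default_study):
        fit1 = fit_iauc_mixed_model(default_records, default_study.meals)
        rng = np.random.default_rng(0)
        shuffled = list(default_records)
        rng.shuffle(shuffled)
        fit2 = fit_iauc_mixed_model(shuffled, default_study.meals)
        for k in fit1.betas:
            assert fit1.betas[k] == pytest.approx(fit2.betas[k], rel=1e-8)


def _bridge_records(iauc, gl):
    return [
        GlycemicRecord(f"P{i}", f"m{i}", x, 4000.0, 50.0, y)
        for i, (x, y) in enumerate(zip(iauc, gl))
    ]


class TestBridge:
    def test_exact_recovery_on_noiseless_line(self):
        iauc = np.array([20.0, 30.0, 40.0, 55.0, 70.0])
        gl = -22.07 + 1.12 * iauc
        fit = fit_gl_bridge(_bridge_records(iauc, gl))
        assert fit.alpha == pytest.approx(-22.07, abs=1e-10)
        assert fit.beta == pytest.approx(1.12, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_gl_gives_zero_slope(self):
        iauc = np.array([20.0, 30.0, 40.0, 55.0])
        fit = fit_gl_bridge(_bridge_records(iauc, np.full(4, 7.5)))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.alpha == pytest.approx(7.5)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(10, 80, size=200)
        y = 3.0 + 0.7 * x + rng.normal(0, 2, size=200)
        fit = fit_gl_bridge(iauc=x, gl=y)
        X = np.column_stack([np.ones_like(x), x])
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)  # independent oracle
        assert fit.alpha == pytest.approx(beta_hat[0], abs=1e-10)
        assert fit.beta == pytest.approx(beta_hat[1], abs=1e-10)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(9)
        iauc = rng.uniform(500, 6000, size=500)
        gl = -22.07 + 1.12 * iauc + rng.normal(0, 3, size=500)
        fit = fit_gl_bridge(iauc=iauc, gl=gl)
        assert abs(fit.beta - 1.12) < 0.05

    def test_meal_level_aggregation_option(self):
        # two records per meal; meal-level fit sees the means
        recs = _bridge_records([10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
                               [1.0, 3.0, 5.0, 7.0, 9.0, 11.0])
        paired = [
            GlycemicRecord(r.participant_id, f"m{i // 2}", r.iauc, 4000.0, 50.0, r.gl)
            for i, r in enumerate(recs)
        ]
        fit = fit_gl_bridge(paired, level="meal")
        assert fit.n == 3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gl_bridge(iauc=[1.0, 2.0], gl=[1.0, 2.0])
        with pytest.raises(DegenerateRegressionError):
            fit_gl_bridge(iauc=[5.0, 5.0, 5.0], gl=[1.0, 2.0, 3.0])


class TestComposition:
    def test_identity_bridge_returns_iauc_coefficients_verbatim(self):
        f = compose_gl_formula(
            PUBLISHED_IAUC_COEFFICIENTS, GLBridgeCoefficients(0.0, 1.0)
        )
        assert (f.intercept, f.coef_carb, f.coef_fat, f.coef_protein2,
                f.coef_fiber2) == (37.05, 0.35, -0.18, -0.01, -0.01)

    def test_published_pair_composes_to_full_precision_values(self):
        f = compose_gl_formula(
            PUBLISHED_IAUC_COEFFICIENTS, GLBridgeCoefficients(-22.07, 1.12)
        )
        # full-precision composition; the published report rounds these
        assert f.intercept == pytest.approx(19.426, abs=1e-9)
        assert f.coef_carb == pytest.approx(0.392, abs=1e-12)
        assert f.coef_fat == pytest.approx(-0.2016, abs=1e-12)
        assert f.coef_protein2 == pytest.approx(-0.0112, abs=1e-12)
        assert f.coef_fiber2 == pytest.approx(-0.0112, abs=1e-12)

    def test_zero_slope_bridge_leaves_only_its_intercept(self):
        f = compose_gl_formula(
            PUBLISHED_IAUC_COEFFICIENTS, GLBridgeCoefficients(4.5, 0.0)
        )
        assert f.intercept == 4.5
        assert f.coef_carb == f.coef_fat == f.coef_protein2 == f.coef_fiber2 == 0.0

    def test_composition_linearity_on_random_nutrients(self):
        """Predicting through the composed formula equals applying the bridge
        to the iAUC linear predictor, to machine precision."""
        rng = np.random.default_rng(123)
        bridge = GLBridgeCoefficients(-22.07, 1.12)
        formula = compose_gl_formula(PUBLISHED_IAUC_COEFFICIENTS, bridge)
        for _ in range(100):
            carb = rng.uniform(10, 110)
            meal = MealNutrients(
                "m", "m", 300, carb, rng.uniform(0, min(carb, 15)),
                rng.uniform(0, 30), rng.uniform(0, 30), 50,
            )
            via_formula = predict_gl(meal, formula)
            via_bridge = bridge.alpha + bridge.beta * (
                PUBLISHED_IAUC_COEFFICIENTS.linear_predictor(meal)
            )
            assert via_formula == pytest.approx(via_bridge, rel=1e-12, abs=1e-12)


class TestValidation:
    def _summary(self, meal_id, gl_mean):
        return MealSummary(meal_id, 8, 2000.0, 100.0, 50.0, 5.0, gl_mean, 2.0)

    def test_perfect_predictions_give_identity_regression(self):
        meals = VARIED_MEALS
        formula = compose_gl_formula(
            PUBLISHED_IAUC_COEFFICIENTS, GLBridgeCoefficients(-22.07, 1.12)
        )
        summaries = [self._summary(m.meal_id, predict_gl(m, formula)) for m in meals]
        res = validate_predictions(summaries, formula, meals)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-7)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_meals == len(meals)

    def test_doubled_measurements_give_slope_two(self):
        meals = VARIED_MEALS
        formula = compose_gl_formula(
            PUBLISHED_IAUC_COEFFICIENTS, GLBridgeCoefficients(-22.07, 1.12)
        )
        summaries = [
            self._summary(m.meal_id, 2 * predict_gl(m, formula)) for m in meals
        ]
        res = validate_predictions(summaries, formula, meals)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_meals_rejected(self):
        meals = VARIED_MEALS[:2]
        formula = compose_gl_formula(
            PUBLISHED_IAUC_COEFFICIENTS, GLBridgeCoefficients(0.0, 1.0)
        )
        summaries = [self._summary(m.meal_id, 10.0) for m in meals]
        with pytest.raises(InsufficientDataError):
            validate_predictions(summaries, formula, meals)
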