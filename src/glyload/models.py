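"""Model fitting: iAUC mixed model, GL-on-iAUC bridge, composed GL formula.

The modelling chain has three stages:

1. a repeated-measures linear mixed model of iAUC on nutrient composition
   (available carbohydrate, fat, protein^2, fiber^2) with a per-participant
   random intercept, estimated by REML;
2. an ordinary least-squares "bridge" regression of GL on iAUC;
3. the composition of the two, giving a GL prediction formula that needs
   only nutrition-label inputs.

Scale convention: the published nutrient equation lives on a compressed iAUC
axis (values of roughly 25-70), while measured iAUCs are thousands of
mg*min/dL.  ``DEFAULT_IAUC_SCALE`` (mg*min/dL per model unit) converts
between the two; the fitter divides measured iAUC by it, and the synthetic
generator multiplies by it, so coefficients are always reported on the
equation's own scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import GlycemicRecord, MealNutrients, MealSummary, round_half_away
from .errors import (
    DegenerateRegressionError,
    InsufficientDataError,
    JoinError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

#: mg*min/dL of measured iAUC per unit of the nutrient equation's iAUC axis
DEFAULT_IAUC_SCALE = 50.0

#: names of the fixed effects, in design-matrix order (after the intercept)
FIXED_EFFECTS = ("available_carb", "fat", "protein_sq", "fiber_sq")


@dataclass(frozen=True)
class IAUCModelCoefficients:
    """Fixed effects and variance components of the iAUC nutrient model."""

    intercept: float
    beta_carb: float  # per g available carbohydrate
    beta_fat: float  # per g fat
    beta_protein2: float  # per g^2 protein
    beta_fiber2: float  # per g^2 fiber
    participant_variance: float = 0.0
    residual_variance: float = 0.0
    p_values: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    ols_fallback: bool = False

    def linear_predictor(self, meal: MealNutrients) -> float:
        """Mean iAUC (model scale) for a meal's nutrient composition."""
        return (
            self.intercept
            + self.beta_carb * meal.available_carb_g
            + self.beta_fat * meal.fat_g
            + self.beta_protein2 * meal.protein_g**2
            + self.beta_fiber2 * meal.fiber_g**2
        )

    @property
    def betas(self) -> dict:
        return {
            "intercept": self.intercept,
            "available_carb": self.beta_carb,
            "fat": self.beta_fat,
            "protein_sq": self.beta_protein2,
            "fiber_sq": self.beta_fiber2,
        }

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for one fixed effect."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        est = self.betas[name]
        se = self.standard_errors[name]
        return (est - z * se, est + z * se)


#: the published iAUC nutrient equation (model-scale coefficients)
PUBLISHED_IAUC_COEFFICIENTS = IAUCModelCoefficients(
    intercept=37.05,
    beta_carb=0.35,
    beta_fat=-0.18,
    beta_protein2=-0.01,
    beta_fiber2=-0.01,
)


@dataclass(frozen=True)
class GLBridgeCoefficients:
    """Linear map GL = alpha + beta * iAUC (model-scale iAUC)."""

    alpha: float
    beta: float
    r_squared: float = float("nan")
    p_value: float = float("nan")
    n: int = 0


#: the published bridge regression
PUBLISHED_BRIDGE = GLBridgeCoefficients(alpha=-22.07, beta=1.12)


@dataclass(frozen=True)
class GLFormula:
    """GL prediction from nutrition-label composition.

    GL = intercept + coef_carb * (carb - fiber) + coef_fat * fat
       + coef_protein2 * protein^2 + coef_fiber2 * fiber^2
    """

    intercept: float
    coef_carb: float
    coef_fat: float
    coef_protein2: float
    coef_fiber2: float
    version: str = "composed"

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GLFormula":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def rounded(self, ndigits: int = 2) -> dict:
        """Report-style coefficients, rounded half-away-from-zero."""
        out = {}
        for k, v in asdict(self).items():
            if isinstance(v, float):
                scale = 10**ndigits
                out[k] = round_half_away(v * scale) / scale
            else:
                out[k] = v
        return out


@dataclass(frozen=True)
class ValidationResult:
    """Measured-vs-predicted GL regression across meals."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_meals: int


def _design_frame(
    records: Sequence[GlycemicRecord], meals: Sequence[MealNutrients]
) -> pd.DataFrame:
    meal_by_id = {m.meal_id: m for m in meals}
    rows = []
    for r in records:
        meal = meal_by_id.get(r.meal_id)
        if meal is None:
            raise JoinError(f"record references unknown meal_id {r.meal_id!r}")
        rows.append(
            {
                "participant_id": r.participant_id,
                "meal_id": r.meal_id,
                "iauc": r.iauc,
                "gl": r.gl,
                "available_carb": meal.available_carb_g,
                "fat": meal.fat_g,
                "protein_sq": meal.protein_g**2,
                "fiber_sq": meal.fiber_g**2,
            }
        )
    return pd.DataFrame(rows)


def _package_fit(params, bse, pvalues, part_var, resid_var, ols) -> IAUCModelCoefficients:
    names = ("intercept",) + FIXED_EFFECTS
    return IAUCModelCoefficients(
        intercept=float(params[0]),
        beta_carb=float(params[1]),
        beta_fat=float(params[2]),
        beta_protein2=float(params[3]),
        beta_fiber2=float(params[4]),
        participant_variance=float(part_var),
        residual_variance=float(resid_var),
        p_values={n: float(p) for n, p in zip(names, pvalues)},
        standard_errors={n: float(s) for n, s in zip(names, bse)},
        ols_fallback=ols,
    )


def fit_iauc_mixed_model(
    records: Sequence[GlycemicRecord],
    meals: Sequence[MealNutrients],
    iauc_scale: float = DEFAULT_IAUC_SCALE,
) -> IAUCModelCoefficients:
    """REML mixed model of iAUC on nutrients with a participant intercept.

    The response is measured iAUC divided by ``iauc_scale``, so estimates are
    on the published equation's axis.  Falls back to OLS (flagged) when only
    one participant is present or the participant variance collapses to ~0.
    """
    df = _design_frame(records, meals)
    if df.empty or df["meal_id"].nunique() < 2:
        raise InsufficientDataError("need records from at least 2 meals")
    y = df["iauc"].to_numpy() / iauc_scale
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy() for c in FIXED_EFFECTS]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "nutrient design matrix is rank-deficient "
            "(meals do not vary independently in all four terms)"
        )

    def _ols_fit(flag: bool) -> IAUCModelCoefficients:
        res = sm.OLS(y, X).fit()
        return _package_fit(res.params, res.bse, res.pvalues, 0.0, res.mse_resid, flag)

    if df["participant_id"].nunique() < 2:
        logger.warning("single participant: mixed model degenerates, using OLS")
        return _ols_fit(True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MixedLM warns when var -> boundary
        try:
            model = sm.MixedLM(y, X, groups=df["participant_id"].to_numpy())
            res = model.fit(reml=True)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed model failed (%s); falling back to OLS", exc)
            return _ols_fit(True)
    part_var = float(np.asarray(res.cov_re).ravel()[0])
    resid_var = float(res.scale)
    if not np.isfinite(part_var) or part_var <= 1e-8 * max(resid_var, 1e-12):
        logger.warning("participant variance collapsed to ~0; refitting as OLS")
        return _ols_fit(True)
    k = X.shape[1]
    return _package_fit(
        res.params[:k], res.bse[:k], res.pvalues[:k], part_var, resid_var, False
    )


def fit_gl_bridge(
    records: Optional[Sequence[GlycemicRecord]] = None,
    *,
    iauc: Optional[Sequence[float]] = None,
    gl: Optional[Sequence[float]] = None,
    iauc_scale: float = 1.0,
    level: str = "record",
) -> GLBridgeCoefficients:
    """OLS of GL on iAUC.

    By default fits at record (participant x meal) level; ``level="meal"``
    aggregates to per-meal means first.  ``iauc_scale`` divides the regressor
    so the slope can be reported on the published equation's iAUC axis.
    Raw ``iauc``/``gl`` arrays may be passed instead of records.
    """
    if records is not None:
        df = pd.DataFrame(
            {
                "meal_id": [r.meal_id for r in records],
                "iauc": [r.iauc for r in records],
                "gl": [r.gl for r in records],
            }
        )
        if level == "meal":
            df = df.groupby("meal_id", as_index=False)[["iauc", "gl"]].mean()
        elif level != "record":
            raise ValueError(f"unknown bridge level {level!r}")
        x = df["iauc"].to_numpy(dtype=float)
        y = df["gl"].to_numpy(dtype=float)
    else:
        if iauc is None or gl is None:
            raise InsufficientDataError("provide records or both iauc and gl")
        x = np.asarray(iauc, dtype=float)
        y = np.asarray(gl, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask] / iauc_scale, y[mask]
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 records with finite GL and iAUC, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("iAUC has zero variance; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return GLBridgeCoefficients(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=int(x.size),
    )


def compose_gl_formula(
    iauc_model: IAUCModelCoefficients, bridge: GLBridgeCoefficients
) -> GLFormula:
    """Substitute the iAUC nutrient equation into the GL bridge.

    Performed at full floating precision; rounding happens only at report
    time (``GLFormula.rounded``).
    """
    return GLFormula(
        intercept=bridge.alpha + bridge.beta * iauc_model.intercept,
        coef_carb=bridge.beta * iauc_model.beta_carb,
        coef_fat=bridge.beta * iauc_model.beta_fat,
        coef_protein2=bridge.beta * iauc_model.beta_protein2,
        coef_fiber2=bridge.beta * iauc_model.beta_fiber2,
        version="composed",
    )


def validate_predictions(
    meal_summaries: Sequence[MealSummary],
    formula: GLFormula,
    meals: Sequence[MealNutrients],
) -> ValidationResult:
    """Regress measured mean GL on formula-predicted GL across meals."""
    from .predict import predict_gl  # local import: predict depends on models

    meal_by_id = {m.meal_id: m for m in meals}
    xs, ys = [], []
    for s in meal_summaries:
        meal = meal_by_id.get(s.meal_id)
        if meal is None:
            raise JoinError(f"summary references unknown meal_id {s.meal_id!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # calibration warnings irrelevant here
            xs.append(predict_gl(meal, formula))
        ys.append(s.gl_mean)
    if len(xs) < 3:
        raise InsufficientDataError(f"need >= 3 meals to validate, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("predicted GL has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ValidationResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n_meals=len(xs),
    )
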