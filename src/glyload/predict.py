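"""Apply a GL formula (fitted or published) to nutrition-label inputs."""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import pandas as pd

from .core import MealNutrients
from .errors import InputError
from .models import GLFormula

#: calibration envelope of available carbohydrate in the source study (g)
CALIBRATION_CARB_RANGE = (20.0, 103.0)

#: the published composed GL prediction formula
PUBLISHED_GL_FORMULA = GLFormula(
    intercept=19.27,
    coef_carb=0.39,
    coef_fat=-0.21,
    coef_protein2=-0.01,
    coef_fiber2=-0.01,
    version="published-2021",
)


class CalibrationWarning(UserWarning):
    """Input outside the nutrient envelope the formula was fitted on."""


def predict_gl(meal: MealNutrients, formula: GLFormula) -> float:
    """GL = intercept + c*(carb - fiber) + f*fat + p*protein^2 + b*fiber^2.

    Sugars, if present, are ignored: the formula carries no sugars term.
    Negative predictions are returned as-is with a warning; available
    carbohydrate outside the calibration envelope also warns.
    """
    for fld in ("carb_g", "fiber_g", "protein_g", "fat_g"):
        v = getattr(meal, fld)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise InputError(f"meal {meal.meal_id}: missing nutrient {fld!r}")
    ac = meal.available_carb_g
    lo, hi = CALIBRATION_CARB_RANGE
    if not lo <= ac <= hi:
        warnings.warn(
            f"meal {meal.meal_id}: available carbohydrate {ac:.1f} g is outside "
            f"the calibration envelope [{lo:.0f}, {hi:.0f}] g",
            CalibrationWarning,
            stacklevel=2,
        )
    gl = (
        formula.intercept
        + formula.coef_carb * ac
        + formula.coef_fat * meal.fat_g
        + formula.coef_protein2 * meal.protein_g**2
        + formula.coef_fiber2 * meal.fiber_g**2
    )
    if gl < 0:
        warnings.warn(
            f"meal {meal.meal_id}: predicted GL {gl:.2f} is negative "
            "(composition outside the formula's calibration)",
            CalibrationWarning,
            stacklevel=2,
        )
    return float(gl)


def predict_table(
    meals: Sequence[MealNutrients], formula: GLFormula
) -> pd.DataFrame:
    """Row-wise GL predictions, order preserved.

    Input errors are re-raised with the offending row index.
    """
    rows = []
    for i, meal in enumerate(meals):
        try:
            rows.append({"meal_id": meal.meal_id, "predicted_gl": predict_gl(meal, formula)})
        except InputError as exc:
            raise InputError(f"row {i}: {exc}") from exc
    return pd.DataFrame(rows, columns=["meal_id", "predicted_gl"])
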