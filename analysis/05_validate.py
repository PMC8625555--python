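"""Validate the composed GL formula against measured meal-level GL.

Regresses each meal's measured mean GL (from the cleaned records) on the
formula's prediction from label nutrients alone.  Writes validation.json
and a measured-vs-predicted scatter (SVG).
"""

import argparse
import dataclasses
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("svg")
import matplotlib.pyplot as plt
import numpy as np

from glyload import GLFormula, summarize_by_meal, validate_predictions
from glyload.predict import CalibrationWarning, predict_gl
from glyload.io import read_meals, read_records, write_json, write_manifest


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_records(args.dir / "records_clean.csv")
    meals = read_meals(args.dir / "meals.csv")
    formula = GLFormula.from_json(args.dir / "gl_formula.json")
    summaries = summarize_by_meal(records)
    result = validate_predictions(summaries, formula, meals)
    write_json(dataclasses.asdict(result), args.dir / "validation.json")

    meal_by_id = {m.meal_id: m for m in meals}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CalibrationWarning)
        x = np.array([predict_gl(meal_by_id[s.meal_id], formula) for s in summaries])
    y = np.array([s.gl_mean for s in summaries])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=25, alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 2)
    ax.plot(xs, result.intercept + result.slope * xs, "k-", lw=1)
    ax.set_xlabel("predicted GL (from label nutrients)")
    ax.set_ylabel("measured mean GL per meal")
    ax.set_title(
        f"measured = {result.intercept:.2f} + {result.slope:.2f} x predicted, "
        f"$R^2$ = {result.r_squared:.2f}"
    )
    fig.tight_layout()
    fig.savefig(args.dir / "validation_scatter.svg")
    write_manifest(args.dir, "validate", n_meals=result.n_meals)
    print(
        f"measured GL = {result.intercept:.2f} + {result.slope:.2f} x predicted GL "
        f"across {result.n_meals} meals; R^2 = {result.r_squared:.2f} "
        f"(p = {result.p_value:.2g})"
    )


if __name__ == "__main__":
    main()
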