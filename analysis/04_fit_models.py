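"""Fit the iAUC mixed model and the GL bridge; compose the GL formula.

Stage 1: REML mixed model of iAUC (model scale) on available carbohydrate,
fat, protein^2 and fiber^2 with a participant random intercept.
Stage 2: OLS of GL on iAUC.  Stage 3: substitute 1 into 2, giving
GL = a + b*availCarb + c*fat + d*protein^2 + e*fiber^2.
Writes iauc_model.json, bridge.json and gl_formula.json.
"""

import argparse
import dataclasses
from pathlib import Path

from glyload import compose_gl_formula, fit_gl_bridge, fit_iauc_mixed_model
from glyload.models import DEFAULT_IAUC_SCALE
from glyload.io import read_meals, read_records, write_json, write_manifest


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    ap.add_argument("--bridge-level", choices=("record", "meal"), default="record")
    args = ap.parse_args()

    records = read_records(args.dir / "records_clean.csv")
    meals = read_meals(args.dir / "meals.csv")

    iauc_model = fit_iauc_mixed_model(records, meals)
    bridge = fit_gl_bridge(
        records, iauc_scale=DEFAULT_IAUC_SCALE, level=args.bridge_level
    )
    formula = compose_gl_formula(iauc_model, bridge)

    write_json(dataclasses.asdict(iauc_model), args.dir / "iauc_model.json")
    write_json(dataclasses.asdict(bridge), args.dir / "bridge.json")
    formula.to_json(args.dir / "gl_formula.json")
    write_manifest(args.dir, "fit", n_records=len(records))

    b = iauc_model.betas
    print(
        "iAUC model (model scale): "
        f"{b['intercept']:.2f} + {b['available_carb']:.3f}*availCarb "
        f"{b['fat']:+.3f}*fat {b['protein_sq']:+.4f}*protein^2 "
        f"{b['fiber_sq']:+.4f}*fiber^2"
        + ("  [OLS fallback]" if iauc_model.ols_fallback else "")
    )
    print(
        f"bridge: GL = {bridge.alpha:.2f} + {bridge.beta:.3f}*iAUC "
        f"(R^2 {bridge.r_squared:.2f}, n {bridge.n})"
    )
    r = formula.rounded()
    print(
        f"composed: GL = {r['intercept']} + {r['coef_carb']}*availCarb "
        f"{r['coef_fat']:+}*fat {r['coef_protein2']:+}*protein^2 "
        f"{r['coef_fiber2']:+}*fiber^2"
    )


if __name__ == "__main__":
    main()
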