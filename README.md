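# glyload

Glycemic index (GI) and glycemic load (GL) analysis for **mixed meals**,
with a nutrition-label GL prediction formula.

GI and GL tables exist mostly for single foods, but people increasingly eat
commercially packaged ready-to-eat (RTE) meals whose glycemic impact depends
on the whole composition — fat, protein and fiber all blunt the glucose
response that carbohydrate drives. `glyload` implements the full analysis
chain used to derive and check a label-based GL predictor:

1. **iAUC** — incremental area under the postprandial glucose curve
   (readings at 0, 15, 30, 45, 60, 90, 120 min; baseline = fasting value;
   only area above baseline counts, by the standard ISO/Wolever incremental
   method),
2. **GI** = 100 × iAUC(meal) / iAUC(sugar reference), computed per
   participant against that participant's own carbohydrate-matched
   (25/50/75 g) sugar-solution reference,
3. **GL** = GI × available carbohydrate / 100, where available (net)
   carbohydrate = total carbohydrate − dietary fiber,
4. **cleaning rules** — drop records with fiber > 13 g *and*
   iAUC > 4000 mg·min/dL, or GI outside (10, 100),
5. **two-stage model** — a repeated-measures mixed model
   `iAUC = β₀ + β₁·availCarb + β₂·fat + β₃·protein² + β₄·fiber²`
   (participant random intercept, REML), an OLS bridge `GL = α + β·iAUC`,
   and their composition
   `GL = (α + β·β₀) + β·β₁·availCarb + β·β₂·fat + β·β₃·protein² + β·β₄·fiber²`,
6. **validation** — regression of measured meal-level GL on predicted GL.

Because individual-level trial data are not publicly deposited, the package
ships a synthetic study generator that emulates the trial design
(34 participants in 4 groups, 32 meals, duplicate sugar references per
tier, ≥ 8 eaters per meal) with the published nutrient equation as
generating truth, so every downstream stage is exercised and checkable
against known parameters. The printed 32-meal nutrient/GI/GL table is
packaged as a fixture, and the published formula

```
GL = 19.27 + 0.39·availCarb − 0.21·fat − 0.01·protein² − 0.01·fiber²
```

is available frozen as `PUBLISHED_GL_FORMULA` for direct label-based
prediction.

## Worked example

The analysis is organised as numbered drivers under `analysis/`, each a
thin script over the library:

```bash
python analysis/01_simulate.py --seed 42 --out results
python analysis/02_compute_glycemic.py --dir results
python analysis/03_filter.py --dir results
python analysis/04_fit_models.py --dir results
python analysis/05_validate.py --dir results
python analysis/06_predict_published.py --dir results
```

prints (seed 42):

```
simulated 34 participants, 32 meals, 476 glucose curves (204 sugar references) -> results/
272 records over 32 meals; GI mean 61.2 (range 13.1-130.1), GL mean 28.2
retained 263/272 records (fiber/iAUC: 0, GI<10: 0, GI>100: 9)
iAUC model (model scale): 33.63 + 0.408*availCarb -0.339*fat -0.0036*protein^2 -0.0075*fiber^2
bridge: GL = -15.10 + 0.879*iAUC (R^2 0.70, n 263)
composed: GL = 14.47 + 0.36*availCarb -0.3*fat +0.0*protein^2 -0.01*fiber^2
measured GL = -18.31 + 1.65 x predicted GL across 32 meals; R^2 = 0.91 (p = 1.6e-17)
predicted GL for 32 packaged meals with the published formula; correlation with printed meal-level GL: r = 0.90
GL self-consistency: 27/32 printed rows within 0.5 of GI x availCarb/100 (rounding-consistent); 5 differ (unrounded per-participant averaging upstream)
```

Reading this: one simulated trial produces 272 participant×meal records;
nine are dropped for GI > 100; the refit nutrient equation
(0.408 per g carbohydrate vs the generating 0.35) and the composed formula
are recovered from the noisy data; and the predicted GL explains 91% of
between-meal variance in measured GL, with a calibration slope above 1 —
the same under-dispersion pattern the formula shows on real meals. Library
use is a few lines:

```python
from glyload import MealNutrients, PUBLISHED_GL_FORMULA, predict_gl

meal = MealNutrients("x", "bibimbap bowl", kcal=520, carb_g=80, fiber_g=6,
                     protein_g=18, fat_g=12, tier_g=75)
print(predict_gl(meal, PUBLISHED_GL_FORMULA))  # 42.01
```

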