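# Methods

## Incremental AUC

The baseline is the single fasting reading at t = 0 (the protocol records
one fasting value; no averaging). The glucose trajectory is treated as
piecewise linear between the seven grid readings, and the iAUC is the exact
integral of `max(g(t) − g(0), 0)` over 0–120 min: segments entirely above
baseline contribute trapezoids, segments crossing baseline contribute only
the triangular part above it, and segments entirely below contribute
nothing (areas below baseline are excluded, not netted — the standard
incremental method). The unit test oracle is an independent fine-grid
(0.001 min) trapezoid quadrature of the clipped interpolant; the two agree
to 1e−6 relative error on random curves with below-baseline dips.

## GI and GL

GI is a within-participant ratio: each meal test is divided by the *same
participant's* mean sugar-reference iAUC at the matching carbohydrate tier
(25/50/75 g; duplicate references are averaged, a single repeat is accepted
with a warning). Meal-level GI is the mean of per-participant GIs — not the
ratio of mean iAUCs, which differs whenever references vary between people.
GL = GI × available carbohydrate / 100 with available carbohydrate = total
carbohydrate − dietary fiber. Report-style integers round half away from
zero. Tier matching uses the explicit `tier_g` column, never nearest-dose
inference. Curves with other `test_type` labels (e.g. a boiled-rice
standard) pass through I/O untouched and never enter GI computation.

## The iAUC scale convention

The published nutrient equation
`iAUC = 37.05 + 0.35·availCarb − 0.18·fat − 0.01·protein² − 0.01·fiber²`
and the bridge `GL = −22.07 + 1.12·iAUC` are dimensionally consistent with
GL values of 4–54 only if "iAUC" in them denotes a compressed axis: the
linear predictor spans ≈ 37–70 while measured meal areas span
≈ 1400–6000 mg·min/dL. This package therefore carries a single conversion
factor, `iauc_scale` (mg·min/dL per model unit, default **50**), used
symmetrically: the simulator sets mean meal iAUC to `iauc_scale ×` linear
predictor, and `fit_iauc_mixed_model` divides measured iAUC by it before
fitting, so estimated coefficients are always reported on the equation's
own axis. The default 50 places simulated meal iAUCs (≈ 1900–3300) and GIs
(≈ 50–80) inside the ranges observed for real mixed meals at these tiers;
it is a calibration convention of this package, not a measured constant,
and recovery tests are invariant to its value because generation and
fitting share it.

## Synthetic study generator

What it emulates: the trial design (34 participants in 4 groups of 9/9/8/8;
32 meals assigned round-robin so each group eats 8 meals spanning all
tiers and every meal is eaten by ≥ 8 participants; two sugar references per
tier per participant), fasting baselines `Normal(92.5, 5.4²)` mg/dL,
additive participant heterogeneity on the iAUC scale
(`Normal(0, 400²)` mg·min/dL random intercept), test-level residual noise
(`Normal(0, 500²)` mg·min/dL), and participant-level reference
responsiveness (multiplicative, CV 0.10, shared across tiers) with small
repeat-to-repeat jitter (CV 0.05) so duplicate references differ as real
ones do. Within-participant variance components are not published for this
design; the 400/500 defaults are free calibration choices that give
meal-level GI standard deviations of roughly 10–20 GI units, matching the
printed per-meal spreads. Per-tier mean reference areas default to
2900/4200/5400 mg·min/dL, inside the span of observed sugar-reference
areas. Negative iAUC draws are truncated to zero (logged) rather than
resampled; truncation is rare (< 0.2%) at default noise.

Excursion shape: `Δg(t) = A·(t/t_peak)·exp(1 − t/t_peak)` with
t_peak = 30 min, A solved in closed form so the 7-point trapezoid iAUC
equals the target exactly. The shape rises, peaks once and declines —
qualitatively right for 0–120 min postprandial glucose — and never dips
below baseline, which makes the target iAUC exactly controllable. It does
**not** emulate late undershoot, meter quantization, missing readings, or
meal-specific curve shapes; passing tests therefore demonstrate correctness
of the computational chain under the stated model, not robustness to those
real-data features.

Determinism: one `numpy` generator seeded from `config.seed` drives every
draw in a fixed order; identical configs give byte-identical CSVs.

## Cleaning rules

A record is excluded iff (fiber > 13 g AND iAUC > 4000 mg·min/dL) or
GI < 10 or GI > 100. The fiber rule is a conjunction and all bounds are
strict; records sitting exactly on a bound are retained and logged. A
record failing several rules is counted once, under the first rule in the
order fiber/iAUC → GI-low → GI-high. Filtering is applied at the record
(participant × meal) level — GI is a per-participant quantity — although
whether cleaning should drop whole meals instead is genuinely open; the
report records every exclusion so the choice is auditable.

## Model fitting

The iAUC stage is a linear mixed model with the four fixed effects
(available carbohydrate, fat, protein², fiber² — protein and fiber enter
squared only, no linear terms, and no model selection is performed) and a
random intercept per participant, the minimal structure consistent with a
repeated-measures design; estimation is REML via `statsmodels.MixedLM`,
with Wald p-values and standard errors. If only one participant is present
or the participant variance collapses to ~0 the fit falls back to OLS and
is flagged (`ols_fallback`). A rank-deficient nutrient design raises
immediately.

The bridge is plain OLS of GL on iAUC at record level by default
(preserving sample size); a meal-level option aggregates to per-meal means
first. Composition is exact arithmetic on unrounded coefficients:
`intercept = α + β·β₀`, each nutrient coefficient `= β·βᵢ`; rounding to two
decimals happens only at report time. Composing the *published rounded*
pair gives intercept 19.426 and fat −0.2016, slightly different from the
published composed values 19.27 and −0.21 — the original composition
evidently used unrounded estimates, which are not recoverable; this package
documents the discrepancy rather than adjusting either set.

Validation regresses measured mean GL per meal on the formula's prediction
from label nutrients. On default synthetic data the slope exceeds 1 with a
negative intercept — the formula under-disperses predictions relative to
measured GL, the same qualitative calibration pattern reported for real
meals — and R² is well above 0.5. The slope/intercept are reported without
recalibration.

## Numerical and interface choices

* CSV I/O is locale-independent (UTF-8, period decimals) and bit-exact on
  round-trip (`float_precision="round_trip"` on read).
* Missing sugars values ("N/A" on one packaged label) stay missing — sugars
  are not a model term and are never imputed.
* The packaged 32-meal table is transcribed verbatim, including three GI SD
  cells (70, 50, 80) that are presumed typesetting artifacts; they carry an
  `anomaly` flag and are never used as expected values. A per-row
  consistency check compares printed GL against GI × availCarb/100; only
  rounding-consistent rows serve as worked examples.
* Predictions outside the calibration envelope (available carbohydrate
  20–103 g, the packaged table's span) or below zero warn
  (`CalibrationWarning`) but return the computed value.
* Problem sizes in tests and the acceptance script follow the trial design
  (34 participants, 32 meals, 272 records; 20 replicates for recovery
  checks; 500 records for the bridge simulation), which keeps every run in
  the seconds-to-a-minute range.

## Known limitations

* The generator's noise model is additive-Gaussian on the iAUC scale with a
  single random intercept; real repeated-measures glycemic data show
  skewness, heteroscedasticity across tiers, and day effects.
* GI > 100 exclusions interact with the reference-tier calibration: higher
  `ref_participant_cv` inflates the excluded fraction and slightly biases
  refit coefficients; defaults keep exclusions below ~5%.
* The published formula targets GL only; no GI prediction, no
  low/medium/high classification, no insulin or gastric-emptying modelling,
  and no extrapolation beyond 120 min.
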