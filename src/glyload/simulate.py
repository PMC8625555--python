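"""Synthetic glycemic-response study generator.

Emulates a crossover-style feeding study: 34 healthy adults split into 4
groups of 8-9, each group eating 8 of 32 mixed meals, with duplicate
sugar-solution references at the 25/50/75 g carbohydrate tiers.  Meal-level
mean iAUC follows a known linear nutrient equation (the generating truth),
participants contribute an additive random intercept on the iAUC scale, and
each test adds independent residual noise, so downstream model fitting can
be checked against ground truth.

Glucose excursions use a single-peak gamma-type shape
``delta_g(t) = A * (t/peak) * exp(1 - t/peak)`` whose amplitude ``A`` is
solved so the trapezoidal iAUC on the 7-point grid equals the requested
target exactly.  The shape never dips below baseline, which keeps the iAUC
controllable; real curves can undershoot after 60 min, which this generator
deliberately does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import TIME_GRID, GlucoseCurve, MealNutrients
from .errors import ConfigError
from .models import DEFAULT_IAUC_SCALE, IAUCModelCoefficients, PUBLISHED_IAUC_COEFFICIENTS

logger = logging.getLogger(__name__)

#: default per-tier mean reference iAUC (mg*min/dL); calibration defaults
#: sitting inside the span of observed sugar-reference areas, not measured
#: constants.
DEFAULT_REF_IAUC_BY_TIER = {25: 2900.0, 50: 4200.0, 75: 5400.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters of the synthetic study."""

    n_participants: int = 34
    n_groups: int = 4
    meals_per_group: int = 8
    time_grid: tuple[float, ...] = TIME_GRID
    baseline_mean: float = 92.5  # mg/dL fasting glucose
    baseline_sd: float = 5.4
    participant_sd: float = 400.0  # SD of participant intercept, mg*min/dL
    residual_sd: float = 500.0  # SD of test-level iAUC noise, mg*min/dL
    ref_iauc_by_tier: dict = field(
        default_factory=lambda: dict(DEFAULT_REF_IAUC_BY_TIER)
    )
    true_coefficients: IAUCModelCoefficients = PUBLISHED_IAUC_COEFFICIENTS
    iauc_scale: float = DEFAULT_IAUC_SCALE  # mg*min/dL per model unit
    ref_participant_cv: float = 0.10  # participant-level reference multiplier
    ref_repeat_cv: float = 0.05  # repeat-to-repeat reference jitter
    peak_time: float = 30.0  # minutes
    random_meals: bool = False  # sample compositions instead of the fixture
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ConfigError("time_grid must be strictly increasing from 0")
        for fld in ("baseline_sd", "participant_sd", "residual_sd",
                    "ref_participant_cv", "ref_repeat_cv"):
            if getattr(self, fld) < 0:
                raise ConfigError(f"{fld} must be >= 0")
        if any(v <= 0 for v in self.ref_iauc_by_tier.values()):
            raise ConfigError("reference iAUC tier means must be > 0")
        if not 0 < self.peak_time < grid[-1]:
            raise ConfigError("peak_time must lie inside the grid span")
        if self.n_participants < self.n_groups:
            raise ConfigError("need at least one participant per group")
        if self.iauc_scale <= 0:
            raise ConfigError("iauc_scale must be > 0")


@dataclass(frozen=True)
class ParticipantProfile:
    """One simulated participant with their random effect."""

    participant_id: str
    group: int
    baseline_glucose: float  # mg/dL
    random_intercept: float  # mg*min/dL, Normal(0, participant_sd^2)

    def __post_init__(self) -> None:
        if self.baseline_glucose <= 0:
            raise ConfigError("baseline glucose must be positive")


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete simulated dataset plus its generating truth."""

    config: SimulationConfig
    participants: list
    meals: list
    curves: list
    truth: dict

    @property
    def reference_curves(self) -> list:
        return [c for c in self.curves if c.test_type == "reference"]

    @property
    def meal_curves(self) -> list:
        return [c for c in self.curves if c.test_type == "meal"]


# tier layout of the packaged meal table: 8 meals at 25 g, 16 at 50 g, 8 at 75 g
_FIXTURE_TIERS = (25,) * 8 + (50,) * 16 + (75,) * 8


def generate_meal_table(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[MealNutrients]:
    """The study's 32 mixed meals.

    Default mode returns the packaged nutrient table (printed label values).
    Random mode samples label-plausible compositions per tier, keeping total
    carbohydrate within +/-10% of the tier and clamping fiber to at most the
    carbohydrate mass (clamps are logged).
    """
    n_meals = config.n_groups * config.meals_per_group
    if not config.random_meals:
        from .io import load_table3_fixture

        meals, _ = load_table3_fixture()
        return meals[:n_meals]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tiers = list(_FIXTURE_TIERS)
    if n_meals != len(tiers):  # repeat the tier pattern as needed
        tiers = [_FIXTURE_TIERS[i % len(_FIXTURE_TIERS)] for i in range(n_meals)]
    valid = set(config.ref_iauc_by_tier)
    meals = []
    for i, tier in enumerate(tiers, start=1):
        if tier not in valid:
            raise ConfigError(f"tier {tier} g has no reference iAUC configured")
        carb = tier * rng.uniform(0.9, 1.1)
        fiber = rng.uniform(0.0, 12.0)
        if fiber > carb:
            logger.warning("meal %d: fiber %.1f g clamped to carbohydrate", i, fiber)
            fiber = carb
        sugars = rng.uniform(0.0, min(carb, 20.0))
        protein = rng.uniform(1.0, 25.0)
        fat = rng.uniform(0.0, 25.0)
        meals.append(
            MealNutrients(
                meal_id=str(i),
                name=f"synthetic meal {i}",
                kcal=round(4 * (carb + protein) + 9 * fat),
                carb_g=round(carb, 1),
                fiber_g=round(fiber, 1),
                sugars_g=round(sugars, 1),
                protein_g=round(protein, 1),
                fat_g=round(fat, 1),
                tier_g=tier,
            )
        )
    return meals


def target_iauc(
    meal: MealNutrients,
    profile: ParticipantProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> float:
    """Draw one test's true iAUC (mg*min/dL) for a participant x meal.

    Mean = iauc_scale x nutrient linear predictor; the participant's random
    intercept and Normal(0, residual_sd^2) test noise are added on the
    measured scale, then truncated at zero (truncations are logged).
    """
    lp = config.true_coefficients.linear_predictor(meal)
    value = (
        config.iauc_scale * lp
        + profile.random_intercept
        + rng.normal(0.0, config.residual_sd)
    )
    if value < 0:
        logger.info(
            "participant %s meal %s: iAUC draw %.1f truncated to 0",
            profile.participant_id,
            meal.meal_id,
            value,
        )
        value = 0.0
    return float(value)


def simulate_glucose_curve(
    iauc_target: float,
    baseline: float,
    peak_time: float = 30.0,
    time_grid: Sequence[float] = TIME_GRID,
    **curve_meta,
) -> GlucoseCurve:
    """A 7-point glucose curve whose grid-trapezoid iAUC equals the target.

    The incremental shape is ``A * (t/peak) * exp(1 - t/peak)`` (maximum at
    ``peak_time``); ``A`` is solved in closed form from the trapezoid rule.
    A zero target gives a flat curve at baseline.
    """
    if iauc_target < 0:
        raise ConfigError(f"iAUC target must be >= 0, got {iauc_target}")
    if baseline <= 0:
        raise ConfigError("baseline must be positive")
    t = np.asarray(time_grid, dtype=float)
    if not 0 < peak_time < t[-1]:
        raise ConfigError("peak_time must lie inside the grid span")
    shape = (t / peak_time) * np.exp(1.0 - t / peak_time)
    unit_area = float(np.trapezoid(shape, t))
    amplitude = iauc_target / unit_area
    glucose = baseline + amplitude * shape
    meta = {
        "participant_id": "sim",
        "test_type": "meal",
        "meal_id": "",
        "tier_g": 0,
        "repeat": 1,
    }
    meta.update(curve_meta)
    return GlucoseCurve(
        times=tuple(float(x) for x in t),
        glucose=tuple(float(g) for g in glucose),
        **meta,
    )


def _group_sizes(n: int, groups: int) -> list[int]:
    base, extra = divmod(n, groups)
    return [base + (1 if g < extra else 0) for g in range(groups)]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full study: participants, meals, reference and meal curves.

    Deterministic under ``config.seed``.  Group g receives the meals whose
    (0-based) index is congruent to g modulo ``n_groups``, which spreads each
    carbohydrate tier across groups and guarantees every meal is eaten by at
    least ``floor(n_participants / n_groups)`` participants.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _group_sizes(config.n_participants, config.n_groups)

    participants: list[ParticipantProfile] = []
    pid = 0
    for group, size in enumerate(sizes, start=1):
        for _ in range(size):
            pid += 1
            baseline = max(rng.normal(config.baseline_mean, config.baseline_sd), 40.0)
            participants.append(
                ParticipantProfile(
                    participant_id=f"P{pid:02d}",
                    group=group,
                    baseline_glucose=float(baseline),
                    random_intercept=float(rng.normal(0.0, config.participant_sd)),
                )
            )

    meals = generate_meal_table(config, rng)
    meals_by_group: dict[int, list[MealNutrients]] = {
        g: [] for g in range(1, config.n_groups + 1)
    }
    for i, meal in enumerate(meals):
        meals_by_group[(i % config.n_groups) + 1].append(meal)

    tiers = sorted(config.ref_iauc_by_tier)
    curves: list[GlucoseCurve] = []
    for p in participants:
        # participant-level responsiveness multiplier shared across tiers
        ref_factor = max(1.0 + rng.normal(0.0, config.ref_participant_cv), 0.1)
        for tier in tiers:
            for repeat in (1, 2):
                jitter = max(1.0 + rng.normal(0.0, config.ref_repeat_cv), 0.0)
                target = config.ref_iauc_by_tier[tier] * ref_factor * jitter
                curves.append(
                    simulate_glucose_curve(
                        target,
                        p.baseline_glucose,
                        config.peak_time,
                        config.time_grid,
                        participant_id=p.participant_id,
                        test_type="reference",
                        meal_id="",
                        tier_g=tier,
                        repeat=repeat,
                        group=p.group,
                    )
                )
        for meal in meals_by_group[p.group]:
            curves.append(
                simulate_glucose_curve(
                    target_iauc(meal, p, config, rng),
                    p.baseline_glucose,
                    config.peak_time,
                    config.time_grid,
                    participant_id=p.participant_id,
                    test_type="meal",
                    meal_id=meal.meal_id,
                    tier_g=meal.tier_g,
                    repeat=1,
                    group=p.group,
                )
            )

    truth = {
        "coefficients": config.true_coefficients.betas,
        "iauc_scale": config.iauc_scale,
        "participant_sd": config.participant_sd,
        "residual_sd": config.residual_sd,
        "ref_iauc_by_tier": {str(k): v for k, v in config.ref_iauc_by_tier.items()},
        "seed": config.seed,
    }
    return SyntheticStudy(
        config=config,
        participants=participants,
        meals=meals,
        curves=curves,
        truth=truth,
    )
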