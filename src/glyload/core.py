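"""Incremental AUC, glycemic index and glycemic load computation.

The quantities here follow the standard incremental-area method for
postprandial glycemia: the fasting reading at t = 0 is the baseline, the
glucose trajectory is linearly interpolated between measurements, and only
the area *above* baseline contributes (segments dipping below baseline
contribute the triangular part above it; the area below is ignored, not
netted).  GI is the percentage ratio of a meal's iAUC to the same
participant's carbohydrate-matched sugar-reference iAUC, and
GL = GI x available carbohydrate / 100, where available (net) carbohydrate
is total carbohydrate minus dietary fiber.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    DegenerateReferenceError,
    InputError,
    InsufficientDataError,
    MissingReferenceError,
)

logger = logging.getLogger(__name__)

#: measurement grid (minutes) used by the study protocol
TIME_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (table convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class GlucoseCurve:
    """One participant x test glucose trajectory.

    ``test_type`` is ``"reference"`` for the sugar solution, ``"meal"`` for a
    mixed meal; other labels (e.g. a boiled-rice standard) are carried through
    I/O untouched but never enter GI computation.
    """

    participant_id: str
    test_type: str
    meal_id: str  # empty for reference tests
    tier_g: int  # carbohydrate tier: 25, 50 or 75
    repeat: int
    times: tuple[float, ...] = TIME_GRID
    glucose: tuple[float, ...] = ()
    group: int = 0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.glucose):
            raise InputError(
                f"curve {self.participant_id}/{self.meal_id or 'ref'}: "
                f"{len(self.times)} times but {len(self.glucose)} glucose values"
            )
        t = np.asarray(self.times, dtype=float)
        if len(t) and (t[0] != 0 or np.any(np.diff(t) <= 0)):
            raise InputError("times must be strictly increasing from 0")
        if any(g <= 0 for g in self.glucose):
            raise InputError("glucose readings must be positive")

    @property
    def baseline(self) -> float:
        return self.glucose[0]


@dataclass(frozen=True)
class MealNutrients:
    """Nutrition-label composition of a meal.

    ``sugars_g`` may be ``None`` (printed "N/A" on some labels); sugars are
    not a term of any model here and a missing value never enters computation.
    """

    meal_id: str
    name: str
    kcal: float
    carb_g: float
    fiber_g: float
    protein_g: float
    fat_g: float
    tier_g: int
    sugars_g: Optional[float] = None

    def __post_init__(self) -> None:
        for fld in ("kcal", "carb_g", "fiber_g", "protein_g", "fat_g"):
            v = getattr(self, fld)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise InputError(f"meal {self.meal_id}: missing required field {fld!r}")
            if v < 0:
                raise InputError(f"meal {self.meal_id}: {fld} must be >= 0, got {v}")
        if self.fiber_g > self.carb_g:
            raise InputError(
                f"meal {self.meal_id}: fiber ({self.fiber_g} g) exceeds "
                f"total carbohydrate ({self.carb_g} g)"
            )

    @property
    def available_carb_g(self) -> float:
        """Available (net) carbohydrate: total carbohydrate minus fiber."""
        return self.carb_g - self.fiber_g


@dataclass(frozen=True)
class GlycemicRecord:
    """Derived glycemic quantities for one participant x meal test."""

    participant_id: str
    meal_id: str
    iauc: float  # mg*min/dL
    ref_iauc: float  # mg*min/dL, participant's tier-matched mean reference
    gi: float  # percent
    gl: float  # dimensionless
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass(frozen=True)
class MealSummary:
    """Per-meal mean +/- SD over contributing participants (sample SD, n-1)."""

    meal_id: str
    n: int
    iauc_mean: float
    iauc_sd: float
    gi_mean: float
    gi_sd: float
    gl_mean: float
    gl_sd: float


def incremental_auc(times: Sequence[float], glucose: Sequence[float]) -> float:
    """Exact piecewise-linear incremental AUC above the t=0 baseline.

    Integrates max(g(t) - g(0), 0) over the grid span, where g is the linear
    interpolant of the readings.  A segment crossing the baseline contributes
    only its triangular portion above baseline.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if t.size < 2:
        raise InputError("need at least 2 time points for an iAUC")
    d = g - g[0]  # increments over baseline
    total = 0.0
    for i in range(t.size - 1):
        dt = t[i + 1] - t[i]
        d0, d1 = d[i], d[i + 1]
        if d0 >= 0 and d1 >= 0:
            total += 0.5 * (d0 + d1) * dt
        elif d0 > 0 and d1 < 0:  # falling crossing: triangle on the left
            total += 0.5 * d0 * dt * d0 / (d0 - d1)
        elif d0 < 0 and d1 > 0:  # rising crossing: triangle on the right
            total += 0.5 * d1 * dt * d1 / (d1 - d0)
        # both below baseline: contributes nothing
    return float(total)


def curve_iauc(curve: GlucoseCurve) -> float:
    """Incremental AUC of a :class:`GlucoseCurve`."""
    return incremental_auc(curve.times, curve.glucose)


def reference_iauc(
    curves: Iterable[GlucoseCurve], participant_id: str, tier_g: int
) -> float:
    """Mean iAUC over a participant's duplicate sugar references at a tier.

    The protocol supplies the sugar solution twice per tier; a single repeat
    is accepted with a warning, zero repeats is an error.
    """
    repeats = [
        c
        for c in curves
        if c.test_type == "reference"
        and c.participant_id == participant_id
        and c.tier_g == tier_g
    ]
    if not repeats:
        raise MissingReferenceError(
            f"no reference curve for participant {participant_id!r} "
            f"at tier {tier_g} g"
        )
    if len(repeats) == 1:
        logger.warning(
            "participant %s tier %d g: single reference repeat (expected 2)",
            participant_id,
            tier_g,
        )
    return float(np.mean([curve_iauc(c) for c in repeats]))


def compute_gi(food_iauc: float, ref_iauc: float) -> float:
    """GI = 100 x (iAUC after the food) / (iAUC after the sugar reference)."""
    if ref_iauc <= 0:
        raise DegenerateReferenceError(
            f"reference iAUC must be > 0 to define GI, got {ref_iauc}"
        )
    if food_iauc < 0:
        raise InputError(f"food iAUC must be >= 0, got {food_iauc}")
    return 100.0 * food_iauc / ref_iauc


def compute_gl(gi: float, meal: MealNutrients) -> float:
    """GL = GI x available carbohydrate / 100."""
    if gi < 0:
        raise InputError(f"GI must be >= 0, got {gi}")
    return gi * meal.available_carb_g / 100.0


def compute_records(
    curves: Sequence[GlucoseCurve], meals: Sequence[MealNutrients]
) -> list[GlycemicRecord]:
    """Per participant x meal iAUC, GI and GL from a full set of curves.

    Each meal test is referenced against the *same participant's* tier-matched
    mean sugar reference (GI is a within-participant ratio, averaged across
    participants only at summary time).
    """
    meal_by_id = {m.meal_id: m for m in meals}
    ref_curves = [c for c in curves if c.test_type == "reference"]
    ref_cache: dict[tuple[str, int], float] = {}
    records: list[GlycemicRecord] = []
    for c in curves:
        if c.test_type != "meal":
            continue
        meal = meal_by_id.get(c.meal_id)
        if meal is None:
            raise InputError(f"curve references unknown meal_id {c.meal_id!r}")
        key = (c.participant_id, c.tier_g)
        if key not in ref_cache:
            ref_cache[key] = reference_iauc(ref_curves, *key)
        ref = ref_cache[key]
        iauc = curve_iauc(c)
        gi = compute_gi(iauc, ref)
        records.append(
            GlycemicRecord(
                participant_id=c.participant_id,
                meal_id=c.meal_id,
                iauc=iauc,
                ref_iauc=ref,
                gi=gi,
                gl=compute_gl(gi, meal),
            )
        )
    return records


def summarize_meal(records: Sequence[GlycemicRecord]) -> MealSummary:
    """Mean and sample SD (denominator n-1) of iAUC/GI/GL for one meal.

    Excluded records must be dropped by the caller beforehand.  A single
    record yields SD 0 by convention (logged).
    """
    retained = [r for r in records if not r.excluded]
    if not retained:
        raise InsufficientDataError("no retained records to summarize")
    ids = {r.meal_id for r in retained}
    if len(ids) != 1:
        raise InputError(f"records span multiple meals: {sorted(ids)}")
    n = len(retained)
    if n == 1:
        logger.warning("meal %s: single record, SD reported as 0", retained[0].meal_id)

    def _mean_sd(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if n > 1 else 0.0
        return float(arr.mean()), sd

    iauc_m, iauc_s = _mean_sd([r.iauc for r in retained])
    gi_m, gi_s = _mean_sd([r.gi for r in retained])
    gl_m, gl_s = _mean_sd([r.gl for r in retained])
    return MealSummary(
        meal_id=next(iter(ids)),
        n=n,
        iauc_mean=iauc_m,
        iauc_sd=iauc_s,
        gi_mean=gi_m,
        gi_sd=gi_s,
        gl_mean=gl_m,
        gl_sd=gl_s,
    )


def summarize_by_meal(records: Sequence[GlycemicRecord]) -> list[MealSummary]:
    """One :class:`MealSummary` per meal_id, in first-appearance order."""
    order: dict[str, list[GlycemicRecord]] = {}
    for r in records:
        if not r.excluded:
            order.setdefault(r.meal_id, []).append(r)
    return [summarize_meal(rs) for rs in order.values()]
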