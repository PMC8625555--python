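"""Pre-fit data-cleaning rules for glycemic records.

A record is excluded iff

* its meal's dietary fiber exceeds 13 g AND its iAUC exceeds 4000 mg*min/dL
  (a conjunction: fiber-rich meals can carry implausibly high areas), or
* its GI is below 10 or above 100 (theoretically insignificant values).

Boundaries are strict; records sitting exactly on a threshold are retained
and logged so the sensitivity of the rule is auditable.  Filtering is
applied at the record (participant x meal) level, before model fitting and
before the meal summaries used in validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .core import GlycemicRecord, MealNutrients
from .errors import JoinError

logger = logging.getLogger(__name__)

FIBER_G_THRESHOLD = 13.0
IAUC_THRESHOLD = 4000.0
GI_LOW = 10.0
GI_HIGH = 100.0

RULE_FIBER_IAUC = "fiber_iauc"
RULE_GI_LOW = "gi_low"
RULE_GI_HIGH = "gi_high"


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of one filtering pass; serializes to JSON."""

    n_input: int
    n_excluded_fiber_iauc: int
    n_excluded_gi_low: int
    n_excluded_gi_high: int
    n_retained: int
    excluded_ids: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @property
    def n_excluded(self) -> int:
        return (
            self.n_excluded_fiber_iauc
            + self.n_excluded_gi_low
            + self.n_excluded_gi_high
        )


def _first_matching_rule(record: GlycemicRecord, fiber_g: float) -> str:
    """Rule label for an excluded record, '' if retained.

    A record failing several rules is counted once, under the first match in
    the order fiber/iAUC -> GI-low -> GI-high.
    """
    if fiber_g > FIBER_G_THRESHOLD and record.iauc > IAUC_THRESHOLD:
        return RULE_FIBER_IAUC
    if record.gi < GI_LOW:
        return RULE_GI_LOW
    if record.gi > GI_HIGH:
        return RULE_GI_HIGH
    if record.gi in (GI_LOW, GI_HIGH) or fiber_g == FIBER_G_THRESHOLD or (
        record.iauc == IAUC_THRESHOLD
    ):
        logger.info(
            "record %s/%s sits exactly on a filter boundary (retained)",
            record.participant_id,
            record.meal_id,
        )
    return ""


def apply_exclusions(
    records: Sequence[GlycemicRecord], meals: Sequence[MealNutrients]
) -> tuple[list[GlycemicRecord], FilterReport]:
    """Drop records failing the cleaning rules; keep order of survivors."""
    fiber_by_meal = {m.meal_id: m.fiber_g for m in meals}
    retained: list[GlycemicRecord] = []
    counts = {RULE_FIBER_IAUC: 0, RULE_GI_LOW: 0, RULE_GI_HIGH: 0}
    excluded_ids: list = []
    for r in records:
        if r.meal_id not in fiber_by_meal:
            raise JoinError(f"record references unknown meal_id {r.meal_id!r}")
        rule = _first_matching_rule(r, fiber_by_meal[r.meal_id])
        if rule:
            counts[rule] += 1
            excluded_ids.append(
                {"participant_id": r.participant_id, "meal_id": r.meal_id, "rule": rule}
            )
        else:
            retained.append(r)
    report = FilterReport(
        n_input=len(records),
        n_excluded_fiber_iauc=counts[RULE_FIBER_IAUC],
        n_excluded_gi_low=counts[RULE_GI_LOW],
        n_excluded_gi_high=counts[RULE_GI_HIGH],
        n_retained=len(retained),
        excluded_ids=excluded_ids,
    )
    return retained, report
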