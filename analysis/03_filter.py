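"""Apply the pre-fit cleaning rules to the glycemic records.

Excludes records with fiber > 13 g AND iAUC > 4000 mg*min/dL, and records
with GI < 10 or GI > 100.  Writes records_clean.csv and filter_report.json.
"""

import argparse
from pathlib import Path

from glyload import apply_exclusions
from glyload.io import read_meals, read_records, write_manifest, write_records


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_records(args.dir / "records.csv")
    meals = read_meals(args.dir / "meals.csv")
    retained, report = apply_exclusions(records, meals)
    write_records(retained, args.dir / "records_clean.csv")
    report.to_json(args.dir / "filter_report.json")
    write_manifest(args.dir, "filter", n_retained=report.n_retained)
    print(
        f"retained {report.n_retained}/{report.n_input} records "
        f"(fiber/iAUC: {report.n_excluded_fiber_iauc}, "
        f"GI<10: {report.n_excluded_gi_low}, GI>100: {report.n_excluded_gi_high})"
    )


if __name__ == "__main__":
    main()
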