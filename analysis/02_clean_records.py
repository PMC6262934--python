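"""Apply the seven-rule cleaning to the raw occurrence table.

Reads the raw CSV written by 01_simulate.py, removes genus-only names,
foreign-country rows, ungeorefererenced rows, duplicates, cultivated,
hybrid and naturalized records, and checks the per-rule removal counts
against the generator's truth ledger.  Writes the cleaned CSV next to the
input and the report to results/.
"""

import argparse
import json
from pathlib import Path

from orchidatlas.cleaning import apply_filters, read_occurrences, write_occurrences
from orchidatlas.synth import TruthLedger


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("scratch/study_system"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--country", default="Australia")
    args = parser.parse_args()

    records = read_occurrences(args.datadir / "occurrences.csv")
    retained, report = apply_filters(records, args.country)
    write_occurrences(retained, args.datadir / "occurrences_clean.csv")

    print(f"input rows: {report.input_count}, retained: {report.retained_count}")
    for rule, n in report.removed_by_rule.items():
        print(f"  rule ({rule}): removed {n}")

    ledger = TruthLedger.from_json(args.datadir / "truth.json")
    match = report.removed_by_rule == ledger.expected_removals
    print(f"per-rule counts match the truth ledger exactly: {match}")
    print(f"conservation (input = retained + removed): {report.check_conservation()}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "cleaning_report.json").write_text(
        json.dumps(report.to_dict() | {"ledger_match": match}, indent=2)
    )


if __name__ == "__main__":
    main()
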