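"""Audit every enoxaparin dose against the eGFR-based recommendation.

Classifies each administered dose by its closest preceding eGFR, applying
the audit's own whole-encounter filters (dialysis, weight > 100 kg), and
writes per-dose assessments, the cohort summary and the wrong-dose
breakdown by eGFR band per phase.
"""

import argparse
import json
from pathlib import Path

from akiflow.enoxaparin import (
    assessments_frame,
    cohort_dose_summary,
    encounter_compliance,
    incorrect_dose_breakdown,
)
from akiflow.io import read_chart_events

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    for phase in ("control", "intervention"):
        src = args.data_dir / phase
        encounters = read_chart_events(src / "events.csv", src / "encounters.csv")
        compliances = [encounter_compliance(e) for e in encounters]
        summary = cohort_dose_summary(compliances)
        breakdown = incorrect_dose_breakdown(compliances)
        out = args.results_dir / phase
        out.mkdir(parents=True, exist_ok=True)
        assessments_frame(compliances).to_csv(out / "dose_assessments.csv", index=False)
        breakdown.to_csv(out / "incorrect_dose_breakdown.csv", index=False)
        (out / "dose_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
        frac = summary.incorrect_fraction
        print(
            f"{phase}: {summary.total_doses} doses audited, "
            f"{summary.incorrect_doses} incorrect "
            f"({'n/a' if frac is None else f'{100 * frac:.2f}%'}), "
            f"fully compliant encounters {summary.compliant_encounters}/"
            f"{summary.eligible_encounters}"
        )
        if len(breakdown):
            top = breakdown.iloc[0]
            print(
                f"  most frequent error: {top.dose_mg:.0f} mg given in eGFR band "
                f"{top.egfr_band} (recommended {top.recommended_mg:.0f} mg), "
                f"x{top['count']}"
            )


if __name__ == "__main__":
    main()
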