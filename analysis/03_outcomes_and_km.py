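"""Aggregate per-encounter outcomes into cohort tables and KM curves.

Builds the two-arm outcome table (admission/developed/discharged AKI, max
stage distribution, progression rates) and the discrete daily
Kaplan-Meier curve of remaining AKI-free, per phase.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from akiflow.outcomes import EncounterOutcomes, cohort_outcome_table, km_no_aki

ROOT = Path(__file__).resolve().parents[1]


def load_outcomes(path: Path) -> list:
    frame = pd.read_csv(path)
    outs = []
    for rec in frame.to_dict("records"):
        outs.append(
            EncounterOutcomes(
                encounter_id=str(rec["encounter_id"]),
                admission_stage=None if pd.isna(rec["admission_stage"]) else int(rec["admission_stage"]),
                discharge_stage=None if pd.isna(rec["discharge_stage"]) else int(rec["discharge_stage"]),
                max_stage=int(rec["max_stage"]),
                max_stage_by_day=[
                    None if pd.isna(rec[f"max_stage_day{k}"]) else int(rec[f"max_stage_day{k}"])
                    for k in range(1, 6)
                ],
                progressed_from_1=bool(rec["progressed_from_1"]),
                progressed_2_to_3=bool(rec["progressed_2_to_3"]),
                reached_stage_1=bool(rec["reached_stage_1"]),
                reached_stage_2=bool(rec["reached_stage_2"]),
                first_aki_day=None if pd.isna(rec["first_aki_day"]) else int(rec["first_aki_day"]),
                discharge_day=int(rec["discharge_day"]),
                uo_computable=bool(rec["uo_computable"]),
            )
        )
    return outs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    for phase in ("control", "intervention"):
        outs = load_outcomes(args.results_dir / phase / "outcomes.csv")
        table = cohort_outcome_table(outs)
        km = km_no_aki(outs, max_day=10)
        out = args.results_dir / phase
        (out / "cohort_summary.json").write_text(json.dumps(table.to_dict(), indent=2))
        km.to_frame().to_csv(out / "km_curve.csv", index=False)
        d = table.to_dict()
        print(
            f"{phase}: n={d['n']}, developed AKI {d['developed_aki_pct']:.1f}%, "
            f"any-AKI prevalence {d['any_aki_prevalence_pct']:.1f}%, "
            f"stage-1 progression {d['progressed_from_1_pct']:.1f}% "
            f"({d['progressed_from_1']}/{d['reached_stage_1']}), "
            f"AKI-free at day 5: {km.survival[4]:.3f}"
        )


if __name__ == "__main__":
    main()
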