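"""Apply the exclusion cascade and stage every retained encounter.

Reads the chart-event tables written by 01_simulate_cohorts.py, applies
the fixed-order exclusion cascade with an audit trail, computes the
urine-output, creatinine and combined AKIN stage series, and writes
per-encounter outcomes plus the long-format stage table per phase.
"""

import argparse
from pathlib import Path

from akiflow.io import read_chart_events, write_exclusion_report, write_outcomes_table
from akiflow.outcomes import outcomes_frame
from akiflow.pipeline import run_staging_pipeline, stages_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "results" / "data")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    for phase in ("control", "intervention"):
        src = args.data_dir / phase
        encounters = read_chart_events(src / "events.csv", src / "encounters.csv")
        retained, report, bundles, outcomes = run_staging_pipeline(encounters)
        out = args.out_dir / phase
        out.mkdir(parents=True, exist_ok=True)
        write_outcomes_table(outcomes_frame(outcomes), out / "outcomes.csv")
        stages_frame(bundles).to_csv(out / "stages.csv", index=False)
        write_exclusion_report(report, out / "exclusion_report.json")
        dropped = ", ".join(f"{k}={v}" for k, v in report.excluded.items() if v)
        print(f"{phase}: {report.initial} read, excluded [{dropped}], "
              f"{report.retained} staged -> {out}")


if __name__ == "__main__":
    main()
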