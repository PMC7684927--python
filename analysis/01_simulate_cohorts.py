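"""Generate the two-phase synthetic study cohorts.

Emulates the before/after design: a control-phase cohort (higher stage-1
progression and dosing-error rates, baseline creatinine rarely charted)
and an intervention-phase cohort (lower rates, baseline mostly charted),
written as chart-event CSVs under results/data/.
"""

import argparse
from pathlib import Path

from akiflow.io import write_chart_events
from akiflow.simulate import control_config, generate_two_phase_study, intervention_config

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=17)
    parser.add_argument("--n-per-phase", type=int, default=800)
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results" / "data")
    args = parser.parse_args()

    study = generate_two_phase_study(
        control_config(n_encounters=args.n_per_phase),
        intervention_config(n_encounters=args.n_per_phase),
        master_seed=args.seed,
    )
    for phase in ("control", "intervention"):
        out = args.out_dir / phase
        out.mkdir(parents=True, exist_ok=True)
        encounters = study[phase]["encounters"]
        write_chart_events(encounters, out / "events.csv", out / "encounters.csv")
        study[phase]["truth"].table.to_csv(out / "truth.csv", index=False)
        t = study[phase]["truth"].table
        print(
            f"{phase}: {len(encounters)} encounters (seed {study[phase]['seed']}), "
            f"latent max-stage>0 in {(t.max_stage > 0).mean():.1%}, "
            f"RRT {(t.rrt).mean():.1%} -> {out}"
        )


if __name__ == "__main__":
    main()
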