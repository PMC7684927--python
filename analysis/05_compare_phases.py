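"""Compare the two phases: proportion tests and the sizing simulation.

Runs the pooled two-proportion z-test on the measured outcome counts of
the two synthetic phases, and a Monte-Carlo power analysis of the
one-tailed Fisher exact design used to size such a study.
"""

import argparse
import json
from pathlib import Path

from akiflow.stats import fisher_power_simulation, two_proportion_test

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--seed", type=int, default=17)
    args = parser.parse_args()

    summaries = {}
    for phase in ("control", "intervention"):
        with open(args.results_dir / phase / "cohort_summary.json") as fh:
            summaries[phase] = json.load(fh)
        with open(args.results_dir / phase / "dose_summary.json") as fh:
            summaries[phase]["doses"] = json.load(fh)

    a, b = summaries["control"], summaries["intervention"]
    tests = {}
    for name, (x1, n1, x2, n2) in {
        "developed_aki_in_icu": (a["developed_aki_in_icu"], a["n"],
                                 b["developed_aki_in_icu"], b["n"]),
        "discharged_with_aki": (a["discharged_with_aki"], a["n"],
                                b["discharged_with_aki"], b["n"]),
        "progressed_from_1": (a["progressed_from_1"], a["reached_stage_1"],
                              b["progressed_from_1"], b["reached_stage_1"]),
        "incorrect_doses": (a["doses"]["incorrect_doses"], a["doses"]["total_doses"],
                            b["doses"]["incorrect_doses"], b["doses"]["total_doses"]),
    }.items():
        r = two_proportion_test(x1, n1, x2, n2)
        tests[name] = {"x1": x1, "n1": n1, "x2": x2, "n2": n2,
                       "p1": r.p1, "p2": r.p2, "z": r.z, "p_value": r.p_value}
        print(f"{name}: {x1}/{n1} ({100 * r.p1:.1f}%) vs {x2}/{n2} "
              f"({100 * r.p2:.1f}%), z={r.z:.2f}, p={r.p_value:.4g}")

    # power of the one-tailed Fisher design for a 15% relative reduction in
    # stage-1 progression from the control-phase rate, at the design alpha
    power = fisher_power_simulation(
        baseline_rate=0.42, relative_reduction=0.15, n_per_arm=3000,
        alpha=0.04, replicates=5000, seed=args.seed,
    )
    print(f"Fisher one-tailed power at n=3000/arm, 15% relative reduction "
          f"from 42%: {power.power:.3f}")

    out = args.results_dir / "comparison.json"
    out.write_text(json.dumps({"tests": tests, "power": power.__dict__}, indent=2))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
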