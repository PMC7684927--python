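"""eGFR-based enoxaparin dose-compliance auditing.

Each administered (nonzero) enoxaparin dose is judged against the
recommended daily dose for the closest preceding eGFR: a dose is correct
when it does not exceed the recommendation. The default three-band table —
40 mg/day at eGFR >= 30, 20 mg/day at 20 <= eGFR < 30, contraindicated
(0 mg) below 20 mL/min/1.73 m^2 — is configurable, with half-open bands
[lower, upper). Encounters on renal replacement therapy or weighing more
than 100 kg are excluded from the audit as a whole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from akiflow.model import Encounter


@dataclass(frozen=True)
class DoseRule:
    """One eGFR band [egfr_lower, egfr_upper) -> recommended mg/day."""

    egfr_lower: float
    egfr_upper: float
    recommended_mg: float

    def __post_init__(self) -> None:
        if not self.egfr_lower < self.egfr_upper:
            raise ValueError("band must satisfy lower < upper")
        if self.recommended_mg < 0:
            raise ValueError("recommended dose must be >= 0")


#: Default prophylactic table: two bands anchored by the renal-adjustment
#: guidance (20 mg at eGFR 20-30, none below 20) plus the standard 40 mg
#: prophylactic dose at preserved renal function.
DEFAULT_DOSE_TABLE = (
    DoseRule(0.0, 20.0, 0.0),
    DoseRule(20.0, 30.0, 20.0),
    DoseRule(30.0, math.inf, 40.0),
)


def validate_dose_table(table: Sequence[DoseRule]) -> "tuple[DoseRule, ...]":
    """Check the bands partition [0, inf) and doses are non-decreasing."""
    rules = tuple(sorted(table, key=lambda r: r.egfr_lower))
    if not rules or rules[0].egfr_lower != 0.0 or not math.isinf(rules[-1].egfr_upper):
        raise ValueError("dose table must cover [0, inf)")
    for a, b in zip(rules, rules[1:]):
        if a.egfr_upper != b.egfr_lower:
            raise ValueError(f"dose bands must abut: {a} vs {b}")
        if b.recommended_mg < a.recommended_mg:
            raise ValueError("recommended dose must be non-decreasing in eGFR")
    return rules


def recommended_dose(egfr: float, table: Sequence[DoseRule] = DEFAULT_DOSE_TABLE) -> float:
    """Recommended daily enoxaparin dose (mg) for an eGFR value."""
    if egfr < 0:
        raise ValueError(f"eGFR must be non-negative, got {egfr}")
    for rule in table:
        if rule.egfr_lower <= egfr < rule.egfr_upper:
            return rule.recommended_mg
    raise ValueError(f"dose table does not cover eGFR {egfr}")


@dataclass(frozen=True)
class DoseAssessment:
    """Verdict on one administered dose."""

    encounter_id: str
    dose_time: pd.Timestamp
    dose_mg: float
    preceding_egfr: Optional[float]
    preceding_egfr_time: Optional[pd.Timestamp]
    recommended_mg: Optional[float]
    verdict: str                     # 'correct' | 'incorrect' | 'ineligible'
    ineligibility_reason: Optional[str] = None  # 'no_prior_egfr' | 'rrt' | 'weight_gt_100kg'


def classify_dose(
    encounter_id: str,
    dose_mg: float,
    dose_time,
    egfr_events: pd.DataFrame,
    table: Sequence[DoseRule] = DEFAULT_DOSE_TABLE,
) -> DoseAssessment:
    """Judge one dose against the latest eGFR charted at or before it.

    Doses with no prior eGFR are ineligible (removed from the audit), not
    incorrect.
    """
    if not dose_mg > 0:
        raise ValueError("only nonzero administered doses are assessed")
    dose_time = pd.Timestamp(dose_time)
    times = pd.DatetimeIndex(egfr_events["timestamp"]) if len(egfr_events) else pd.DatetimeIndex([])
    i = times.searchsorted(dose_time, side="right")
    if i == 0:
        return DoseAssessment(encounter_id, dose_time, dose_mg, None, None, None,
                              "ineligible", "no_prior_egfr")
    egfr = float(egfr_events["value"].iloc[i - 1])
    rec = recommended_dose(egfr, table)
    verdict = "correct" if dose_mg <= rec else "incorrect"
    return DoseAssessment(encounter_id, dose_time, dose_mg, egfr, times[i - 1], rec, verdict)


@dataclass
class EncounterCompliance:
    """Dose audit summary for one encounter."""

    encounter_id: str
    eligible: bool
    ineligibility_reason: Optional[str]  # 'rrt' | 'weight_gt_100kg' when not eligible
    assessments: list = field(default_factory=list)

    @property
    def n_correct(self) -> int:
        return sum(a.verdict == "correct" for a in self.assessments)

    @property
    def n_incorrect(self) -> int:
        return sum(a.verdict == "incorrect" for a in self.assessments)

    @property
    def n_ineligible(self) -> int:
        return sum(a.verdict == "ineligible" for a in self.assessments)

    @property
    def fully_compliant(self) -> Optional[bool]:
        """Correct dosing for the entire stay: at least one correct dose and
        no incorrect one. None for encounters outside the audit."""
        if not self.eligible:
            return None
        return self.n_incorrect == 0 and self.n_correct >= 1


def encounter_compliance(
    encounter: Encounter,
    table: Sequence[DoseRule] = DEFAULT_DOSE_TABLE,
    max_weight_kg: float = 100.0,
    mode: str = "per_dose",
) -> EncounterCompliance:
    """Audit every administered dose of one encounter.

    The audit has its own whole-encounter filters, independent of the
    staging cohort's exclusion cascade: renal replacement therapy at any
    point of the stay, or a maximum charted weight above `max_weight_kg`
    (the conservative reading of "weighed more than 100 kg").

    mode='per_dose' (default) judges each administration on its own;
    mode='daily' sums administrations over each 24 h day of stay and
    judges the total against the recommended *daily* dose at the first
    dose of the day — the reading appropriate when the table is meant as
    a per-24 h ceiling under b.i.d. dosing.
    """
    if mode not in ("per_dose", "daily"):
        raise ValueError(f"unknown audit mode {mode!r}")
    if encounter.on_rrt_during_stay():
        return EncounterCompliance(encounter.encounter_id, False, "rrt")
    weights = encounter.events_of("weight")["value"]
    if len(weights) and float(weights.max()) > max_weight_kg:
        return EncounterCompliance(encounter.encounter_id, False, "weight_gt_100kg")
    doses = encounter.events_of("enoxaparin_dose")
    doses = doses[doses["value"] > 0]
    egfr = encounter.events_of("egfr")
    if mode == "daily" and len(doses):
        day = (
            (pd.DatetimeIndex(doses["timestamp"]) - encounter.admission_time)
            // pd.Timedelta(hours=24)
        )
        daily = doses.groupby(day.to_numpy()).agg(
            timestamp=("timestamp", "min"), value=("value", "sum")
        )
        doses = daily.reset_index(drop=True)
    assessments = [
        classify_dose(encounter.encounter_id, float(row.value), row.timestamp, egfr, table)
        for row in doses.itertuples()
    ]
    return EncounterCompliance(encounter.encounter_id, True, None, assessments)


@dataclass
class CohortDoseSummary:
    """Dose-level and encounter-level compliance for one cohort."""

    total_doses: int            # eligible (classified) doses only
    correct_doses: int
    incorrect_doses: int
    removed_doses: int          # no prior eGFR
    eligible_encounters: int    # in-audit encounters with >= 1 classified dose
    compliant_encounters: int

    @property
    def incorrect_fraction(self) -> Optional[float]:
        return self.incorrect_doses / self.total_doses if self.total_doses else None

    @property
    def compliant_fraction(self) -> Optional[float]:
        return (
            self.compliant_encounters / self.eligible_encounters
            if self.eligible_encounters else None
        )

    def to_dict(self) -> dict:
        return {
            "total_doses": self.total_doses,
            "correct_doses": self.correct_doses,
            "incorrect_doses": self.incorrect_doses,
            "removed_doses": self.removed_doses,
            "incorrect_fraction": self.incorrect_fraction,
            "eligible_encounters": self.eligible_encounters,
            "compliant_encounters": self.compliant_encounters,
            "compliant_fraction": self.compliant_fraction,
        }


def cohort_dose_summary(compliances: Sequence[EncounterCompliance]) -> CohortDoseSummary:
    """Aggregate per-encounter audits; fractions over eligible doses only,
    reported as absent (None) when no dose qualifies."""
    correct = incorrect = removed = eligible_enc = compliant = 0
    for c in compliances:
        if not c.eligible:
            continue
        correct += c.n_correct
        incorrect += c.n_incorrect
        removed += c.n_ineligible
        if c.n_correct + c.n_incorrect > 0:
            eligible_enc += 1
            if c.fully_compliant:
                compliant += 1
    return CohortDoseSummary(
        total_doses=correct + incorrect,
        correct_doses=correct,
        incorrect_doses=incorrect,
        removed_doses=removed,
        eligible_encounters=eligible_enc,
        compliant_encounters=compliant,
    )


def incorrect_dose_breakdown(
    compliances: Sequence[EncounterCompliance],
    table: Sequence[DoseRule] = DEFAULT_DOSE_TABLE,
) -> pd.DataFrame:
    """Stratify incorrect doses by eGFR band x given dose.

    The band counts sum to the total incorrect count; the dominant cell in
    practice is the 20-30 band with a 40 mg dose.
    """
    rows = []
    for c in compliances:
        if not c.eligible:
            continue
        for a in c.assessments:
            if a.verdict != "incorrect":
                continue
            band = next(
                r for r in table if r.egfr_lower <= a.preceding_egfr < r.egfr_upper
            )
            rows.append(
                {
                    "egfr_band": f"[{band.egfr_lower:g}, {band.egfr_upper:g})",
                    "dose_mg": a.dose_mg,
                    "recommended_mg": a.recommended_mg,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["egfr_band", "dose_mg", "recommended_mg", "count"])
    frame = pd.DataFrame(rows)
    return (
        frame.groupby(["egfr_band", "dose_mg", "recommended_mg"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values("count", ascending=False)
        .reset_index(drop=True)
    )


def assessments_frame(compliances: Sequence[EncounterCompliance]) -> pd.DataFrame:
    """Tidy per-dose table (the `dose_assessments.csv` layout)."""
    rows = []
    for c in compliances:
        if not c.eligible:
            rows.append(
                {
                    "encounter_id": c.encounter_id, "dose_time": None, "dose_mg": None,
                    "preceding_egfr": None, "recommended_mg": None,
                    "verdict": "ineligible", "ineligibility_reason": c.ineligibility_reason,
                }
            )
            continue
        for a in c.assessments:
            rows.append(
                {
                    "encounter_id": a.encounter_id,
                    "dose_time": a.dose_time,
                    "dose_mg": a.dose_mg,
                    "preceding_egfr": a.preceding_egfr,
                    "recommended_mg": a.recommended_mg,
                    "verdict": a.verdict,
                    "ineligibility_reason": a.ineligibility_reason,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["encounter_id", "dose_time", "dose_mg", "preceding_egfr",
                 "recommended_mg", "verdict", "ineligibility_reason"],
    )
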