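"""Encounter- and cohort-level AKI outcomes.

Per encounter: stage at admission (first evaluation within 6 h), stage at
discharge (at the last urine/creatinine measurement), maximum stage, the
daily maxima for ICU days 1-5, stage-progression flags (1 -> higher,
2 -> 3) and the ICU day of first AKI. Per cohort: counts and proportions in
the shape of a two-arm outcome table, and the discrete daily Kaplan-Meier
curve of remaining AKI-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from akiflow.model import Encounter, StageSeries
from akiflow.staging import StageBundle


def admission_stage(
    combined: StageSeries, admission_time, window_hours: float = 6.0
) -> Optional[int]:
    """Stage of the first combined evaluation within `window_hours` of
    admission; None (unknown) when the first evaluation falls later or the
    series is empty."""
    if not len(combined):
        return None
    first_time, first_stage = combined.times[0], int(combined.stages[0])
    limit = pd.Timestamp(admission_time) + pd.Timedelta(hours=window_hours)
    return first_stage if first_time <= limit else None


def discharge_stage(combined: StageSeries, encounter: Encounter) -> Optional[int]:
    """Combined stage at the timestamp of the last urine-output or
    creatinine measurement; None when nothing was measured."""
    if not len(combined):
        return None
    ev = encounter.events_of("urine_output", "creatinine")
    if not len(ev):
        return None
    return combined.value_at(ev["timestamp"].iloc[-1])


def max_stage_per_day(
    combined: StageSeries,
    admission_time,
    discharge_time,
    n_days: int = 5,
    carry_forward: bool = True,
) -> list:
    """Maximum combined stage per 24 h ICU day, days 1..n_days.

    Day k covers [admission + 24(k-1) h, admission + 24k h). With
    carry_forward (default) the stage standing at the window start counts
    toward the window, because the combined stage is a state that persists
    between evaluations. Days starting at or after discharge are None; a
    day with no evaluation before or inside it is 0 (no AKI observed yet).
    """
    admission_time = pd.Timestamp(admission_time)
    discharge_time = pd.Timestamp(discharge_time)
    out: list = []
    for k in range(n_days):
        start = admission_time + pd.Timedelta(hours=24 * k)
        if start >= discharge_time:
            out.append(None)
            continue
        end = start + pd.Timedelta(hours=24)
        m = combined.max_in(start, end, carry_forward=carry_forward)
        out.append(0 if m is None else m)
    return out


def progression_flags(combined: StageSeries) -> "tuple[bool, bool]":
    """(progressed_from_1, progressed_2_to_3) over consecutive combined
    evaluations: any move from value 1 to a value > 1 (1 -> 3 counts), and
    any move from 2 to 3; each flag latches once per encounter."""
    s = combined.stages
    if len(s) < 2:
        return False, False
    prev, nxt = s[:-1], s[1:]
    from_1 = bool(((prev == 1) & (nxt > 1)).any())
    two_to_three = bool(((prev == 2) & (nxt == 3)).any())
    return from_1, two_to_three


def first_aki_day(combined: StageSeries, admission_time) -> Optional[int]:
    """ICU day (1-based) of the first nonzero combined evaluation; None if
    the encounter never stages.

    Days are the half-open windows [24(k-1), 24k) h from admission, so a
    first event exactly on a day boundary belongs to the day that starts
    there; off boundaries this is the ceiling of elapsed hours / 24.
    """
    nz = np.nonzero(combined.stages > 0)[0]
    if not len(nz):
        return None
    hours = (combined.times[nz[0]] - pd.Timestamp(admission_time)) / pd.Timedelta(hours=1)
    return int(hours // 24.0) + 1


@dataclass
class EncounterOutcomes:
    """All per-encounter outcome quantities in one record."""

    encounter_id: str
    admission_stage: Optional[int]     # None = unknown (first evaluation after 6 h)
    discharge_stage: Optional[int]
    max_stage: int
    max_stage_by_day: list             # length n_days, None past discharge
    progressed_from_1: bool
    progressed_2_to_3: bool
    reached_stage_1: bool              # combined series ever evaluated to exactly 1
    reached_stage_2: bool
    first_aki_day: Optional[int]
    discharge_day: int                 # ceil(LOS / 24 h)
    uo_computable: bool = True

    @property
    def admitted_with_aki(self) -> bool:
        """Unknown admission stage counts as not-admitted-with-AKI (flagged
        separately via admission_stage None)."""
        return self.admission_stage is not None and self.admission_stage >= 1

    @property
    def developed_aki_in_icu(self) -> bool:
        return (not self.admitted_with_aki) and self.max_stage >= 1


def compute_outcomes(
    encounter: Encounter,
    bundle: StageBundle,
    n_days: int = 5,
    admission_window_hours: float = 6.0,
    carry_forward: bool = True,
) -> EncounterOutcomes:
    combined = bundle.combined
    day_max = max_stage_per_day(
        combined, encounter.admission_time, encounter.discharge_time,
        n_days=n_days, carry_forward=carry_forward,
    )
    from_1, two_to_three = progression_flags(combined)
    return EncounterOutcomes(
        encounter_id=encounter.encounter_id,
        admission_stage=admission_stage(combined, encounter.admission_time, admission_window_hours),
        discharge_stage=discharge_stage(combined, encounter),
        max_stage=combined.max_stage,
        max_stage_by_day=day_max,
        progressed_from_1=from_1,
        progressed_2_to_3=two_to_three,
        reached_stage_1=bool((combined.stages == 1).any()),
        reached_stage_2=bool((combined.stages == 2).any()),
        first_aki_day=first_aki_day(combined, encounter.admission_time),
        discharge_day=max(1, math.ceil(encounter.los_hours / 24.0)),
        uo_computable=bundle.uo_computable,
    )


OUTCOME_COLUMNS = [
    "encounter_id",
    "admission_stage",
    "discharge_stage",
    "max_stage",
    "max_stage_day1",
    "max_stage_day2",
    "max_stage_day3",
    "max_stage_day4",
    "max_stage_day5",
    "progressed_from_1",
    "progressed_2_to_3",
    "reached_stage_1",
    "reached_stage_2",
    "first_aki_day",
    "discharge_day",
    "uo_computable",
]


def outcomes_frame(outcomes: Sequence[EncounterOutcomes]) -> pd.DataFrame:
    """Tidy one-row-per-encounter frame (the `outcomes.csv` layout)."""
    rows = []
    for o in outcomes:
        row = {
            "encounter_id": o.encounter_id,
            "admission_stage": o.admission_stage,
            "discharge_stage": o.discharge_stage,
            "max_stage": o.max_stage,
            "progressed_from_1": o.progressed_from_1,
            "progressed_2_to_3": o.progressed_2_to_3,
            "reached_stage_1": o.reached_stage_1,
            "reached_stage_2": o.reached_stage_2,
            "first_aki_day": o.first_aki_day,
            "discharge_day": o.discharge_day,
            "uo_computable": o.uo_computable,
        }
        for k in range(5):
            day = o.max_stage_by_day[k] if k < len(o.max_stage_by_day) else None
            row[f"max_stage_day{k + 1}"] = day
        rows.append(row)
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


# ---------------------------------------------------------------------------
# Kaplan-Meier time-to-first-AKI


@dataclass
class KMCurve:
    """Discrete daily product-limit estimate of remaining AKI-free.

    survival[k] = prod_{j<=k} (1 - events_j / at_risk_j) over ICU days
    1..D; encounters leave the risk set the day after their AKI event or
    discharge. An encounter discharged on day k without AKI still counts
    at risk for day k.
    """

    day: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "n_at_risk": self.n_at_risk,
             "n_events": self.n_events, "survival": self.survival}
        )


def km_no_aki(
    outcomes: Sequence[EncounterOutcomes],
    max_day: int = 10,
    include_admission_aki: bool = True,
) -> KMCurve:
    """Kaplan-Meier curve of the proportion still AKI-free by ICU day.

    Event = first nonzero combined stage (day granularity); censoring =
    discharge without AKI. With include_admission_aki (default) encounters
    already staged at admission are day-1 events; otherwise they are
    dropped from the curve.
    """
    event_day, censor_day = [], []
    for o in outcomes:
        if o.admitted_with_aki and not include_admission_aki:
            continue
        event_day.append(o.first_aki_day if o.first_aki_day is not None else np.inf)
        censor_day.append(o.discharge_day)
    if not event_day:
        return KMCurve(np.arange(1, 0), np.empty(0, int), np.empty(0, int), np.empty(0))
    ed = np.asarray(event_day, dtype=float)
    cd = np.asarray(censor_day, dtype=float)

    days = np.arange(1, max_day + 1)
    at_risk = np.empty(max_day, dtype=int)
    events = np.empty(max_day, dtype=int)
    for i, k in enumerate(days):
        at_risk[i] = int(np.sum((ed >= k) & ((ed < np.inf) | (cd >= k))))
        events[i] = int(np.sum(ed == k))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(at_risk > 0, events / np.maximum(at_risk, 1), 0.0)
    survival = np.cumprod(1.0 - frac)
    return KMCurve(days, at_risk, events, survival)


# ---------------------------------------------------------------------------
# Cohort-level table


def proportion_pct(x: float, n: float) -> Optional[float]:
    """100 * x / n, or None for an empty denominator (never 0-by-fiat)."""
    if n == 0:
        return None
    return 100.0 * x / n


@dataclass
class CohortOutcomeTable:
    """Counts behind a two-arm AKI outcome table, with derived proportions.

    Proportions always come with their denominator: `n` for the admission/
    development/discharge rows, and `n - admitted_with_aki` for the
    max-stage distribution and any-AKI prevalence (the convention that
    reproduces the control-arm published percentages; both numerator and
    denominator are reported because the intervention arm is ambiguous in
    that respect).
    """

    n: int
    admitted_with_aki: int
    admission_stage_unknown: int
    developed_aki_in_icu: int
    discharged_with_aki: int
    max_stage_counts: dict          # stage -> count over all n encounters
    reached_stage_1: int
    progressed_from_1: int
    reached_stage_2: int
    progressed_2_to_3: int

    @property
    def n_not_admitted_with_aki(self) -> int:
        return self.n - self.admitted_with_aki

    def developed_aki_pct(self) -> Optional[float]:
        return proportion_pct(self.developed_aki_in_icu, self.n)

    def discharged_with_aki_pct(self) -> Optional[float]:
        return proportion_pct(self.discharged_with_aki, self.n)

    def max_stage_pct(self, stage: int) -> Optional[float]:
        return proportion_pct(self.max_stage_counts.get(stage, 0), self.n_not_admitted_with_aki)

    def any_aki_prevalence_pct(self) -> Optional[float]:
        any_aki = sum(self.max_stage_counts.get(s, 0) for s in (1, 2, 3))
        return proportion_pct(any_aki, self.n_not_admitted_with_aki)

    def progressed_from_1_pct(self) -> Optional[float]:
        return proportion_pct(self.progressed_from_1, self.reached_stage_1)

    def progressed_2_to_3_pct(self) -> Optional[float]:
        return proportion_pct(self.progressed_2_to_3, self.reached_stage_2)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "admitted_with_aki": self.admitted_with_aki,
            "admission_stage_unknown": self.admission_stage_unknown,
            "developed_aki_in_icu": self.developed_aki_in_icu,
            "developed_aki_pct": self.developed_aki_pct(),
            "discharged_with_aki": self.discharged_with_aki,
            "discharged_with_aki_pct": self.discharged_with_aki_pct(),
            "max_stage_counts": {str(k): v for k, v in sorted(self.max_stage_counts.items())},
            "max_stage_denominator": self.n_not_admitted_with_aki,
            "max_stage_pct": {str(s): self.max_stage_pct(s) for s in (1, 2, 3)},
            "any_aki_prevalence_pct": self.any_aki_prevalence_pct(),
            "reached_stage_1": self.reached_stage_1,
            "progressed_from_1": self.progressed_from_1,
            "progressed_from_1_pct": self.progressed_from_1_pct(),
            "reached_stage_2": self.reached_stage_2,
            "progressed_2_to_3": self.progressed_2_to_3,
            "progressed_2_to_3_pct": self.progressed_2_to_3_pct(),
        }


def cohort_outcome_table(outcomes: Sequence[EncounterOutcomes]) -> CohortOutcomeTable:
    """Aggregate per-encounter outcomes into the two-arm table counts.

    "Developed AKI in ICU" counts encounters not admitted with AKI whose
    maximum stage is >= 1; unknown admission stage counts as not admitted
    with AKI (and is tallied separately).
    """
    max_counts: dict = {0: 0, 1: 0, 2: 0, 3: 0}
    admitted = unknown = developed = discharged = 0
    r1 = p1 = r2 = p23 = 0
    for o in outcomes:
        max_counts[o.max_stage] = max_counts.get(o.max_stage, 0) + 1
        if o.admission_stage is None:
            unknown += 1
        if o.admitted_with_aki:
            admitted += 1
        if o.developed_aki_in_icu:
            developed += 1
        if o.discharge_stage is not None and o.discharge_stage >= 1:
            discharged += 1
        r1 += o.reached_stage_1
        p1 += o.progressed_from_1
        r2 += o.reached_stage_2
        p23 += o.progressed_2_to_3
    return CohortOutcomeTable(
        n=len(outcomes),
        admitted_with_aki=admitted,
        admission_stage_unknown=unknown,
        developed_aki_in_icu=developed,
        discharged_with_aki=discharged,
        max_stage_counts=max_counts,
        reached_stage_1=r1,
        progressed_from_1=p1,
        reached_stage_2=r2,
        progressed_2_to_3=p23,
    )
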