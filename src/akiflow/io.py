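"""Reading/writing chart-event tables and the exclusion cascade.

Input layout: two CSVs. `encounters.csv` carries one row per ICU admission
(encounter_id, admission_time, discharge_time, age, sex, race_black, unit,
admission_type, baseline_creatinine); `events.csv` is long-format
(encounter_id, timestamp, kind, value). Timestamps are ISO-8601 and
timezone-naive; the creatinine unit is declared once per read (mg/dL
canonical, 1 mg/dL = 88.42 umol/L).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from akiflow.model import (
    ADMISSION_TYPES,
    EVENT_KINDS,
    UMOL_PER_MGDL,
    Demographics,
    Encounter,
    ExclusionReport,
)
from akiflow.staging import hourly_uo_rate

CREATININE_UNITS = ("mg/dL", "umol/L")
#: event kinds whose value is a creatinine concentration
_CREATININE_KINDS = ("creatinine", "baseline_creatinine")


def _parse_bool(x) -> Optional[bool]:
    if pd.isna(x):
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {x!r} as boolean")


def read_chart_events(
    events_path,
    encounters_path,
    creatinine_unit: str = "mg/dL",
) -> list:
    """Read the two-table layout into assembled, validated encounters.

    Creatinine-valued events and the charted baseline column are converted
    to mg/dL when the file declares umol/L. RRT start/stop marker events are
    paired into half-open intervals; an unmatched start runs to discharge.

    Raises ValueError naming the offending row for unparseable timestamps,
    unknown event kinds, or negative values.
    """
    if creatinine_unit not in CREATININE_UNITS:
        raise ValueError(f"creatinine_unit must be one of {CREATININE_UNITS}")
    scale = 1.0 / UMOL_PER_MGDL if creatinine_unit == "umol/L" else 1.0

    enc = pd.read_csv(encounters_path)
    ev = pd.read_csv(events_path)

    required = {"encounter_id", "timestamp", "kind", "value"}
    if not required.issubset(ev.columns):
        raise ValueError(f"events table missing columns {sorted(required - set(ev.columns))}")

    bad_kind = ~ev["kind"].isin(EVENT_KINDS)
    if bad_kind.any():
        row = int(np.nonzero(bad_kind.to_numpy())[0][0])
        raise ValueError(f"unknown event kind {ev['kind'].iloc[row]!r} at events row {row}")
    ts = pd.to_datetime(ev["timestamp"], errors="coerce", format="mixed")
    if ts.isna().any():
        row = int(np.nonzero(ts.isna().to_numpy())[0][0])
        raise ValueError(f"unparseable timestamp {ev['timestamp'].iloc[row]!r} at events row {row}")
    ev = ev.assign(timestamp=ts)
    neg = ev["value"].to_numpy(dtype=float) < 0
    if neg.any():
        row = int(np.nonzero(neg)[0][0])
        raise ValueError(f"negative value {ev['value'].iloc[row]} at events row {row}")
    is_cr = ev["kind"].isin(_CREATININE_KINDS)
    ev.loc[is_cr, "value"] = ev.loc[is_cr, "value"] * scale

    grouped = dict(tuple(ev.groupby("encounter_id", sort=False)))
    encounters = []
    for rec in enc.to_dict("records"):
        eid = str(rec["encounter_id"])
        age = rec.get("age")
        demo = Demographics(
            age=None if pd.isna(age) else float(age),
            sex=None if pd.isna(rec.get("sex")) else str(rec["sex"]),
            race_black=_parse_bool(rec.get("race_black")),
            unit=None if pd.isna(rec.get("unit")) else str(rec["unit"]),
            admission_type=(
                None if pd.isna(rec.get("admission_type")) else str(rec["admission_type"])
            ),
        )
        if demo.admission_type is not None and demo.admission_type not in ADMISSION_TYPES:
            raise ValueError(f"unknown admission_type for encounter {eid}")
        baseline = rec.get("baseline_creatinine")
        baseline = None if baseline is None or pd.isna(baseline) else float(baseline) * scale
        events = grouped.get(rec["encounter_id"], ev.iloc[0:0])
        events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
        encounter = Encounter(
            encounter_id=eid,
            demographics=demo,
            admission_time=pd.Timestamp(rec["admission_time"]),
            discharge_time=pd.Timestamp(rec["discharge_time"]),
            events=events[["timestamp", "kind", "value"]],
            charted_baseline_creatinine=baseline,
        )
        encounter.rrt_intervals = _pair_rrt_intervals(encounter)
        encounters.append(encounter)
    return encounters


def _pair_rrt_intervals(encounter: Encounter) -> list:
    starts = list(encounter.events_of("rrt_start")["timestamp"])
    stops = list(encounter.events_of("rrt_stop")["timestamp"])
    intervals = []
    for i, s in enumerate(starts):
        stop = stops[i] if i < len(stops) else encounter.discharge_time
        intervals.append((pd.Timestamp(s), pd.Timestamp(stop)))
    return intervals


def write_chart_events(encounters: Sequence[Encounter], events_path, encounters_path) -> None:
    """Write encounters back to the two-table CSV layout (mg/dL creatinine)."""
    enc_rows = []
    ev_frames = []
    for e in encounters:
        d = e.demographics
        enc_rows.append(
            {
                "encounter_id": e.encounter_id,
                "admission_time": e.admission_time.isoformat(),
                "discharge_time": e.discharge_time.isoformat(),
                "age": d.age,
                "sex": d.sex,
                "race_black": d.race_black,
                "unit": d.unit,
                "admission_type": d.admission_type,
                "baseline_creatinine": e.charted_baseline_creatinine,
            }
        )
        if len(e.events):
            ev_frames.append(e.events.assign(encounter_id=e.encounter_id))
    pd.DataFrame(enc_rows).to_csv(encounters_path, index=False)
    cols = ["encounter_id", "timestamp", "kind", "value"]
    if ev_frames:
        events = pd.concat(ev_frames, ignore_index=True)[cols]
    else:
        events = pd.DataFrame(columns=cols)
    events.to_csv(events_path, index=False)


# ---------------------------------------------------------------------------
# Exclusion cascade


@dataclass(frozen=True)
class ExclusionCriteria:
    """Parameters of the fixed-order exclusion cascade.

    Order (each encounter is counted under the first criterion it fails):
    short stay -> missing demographics -> age over limit -> admission
    oligoanuria -> RRT during stay -> insufficient data.
    """

    min_los_hours: float = 24.0           # strict: stay must exceed this
    max_age_years: float = 90.0           # strict: age must not exceed this
    oligoanuria_window_hours: int = 6
    oligoanuria_rate: float = 0.5         # mL/kg/h mean over the window
    exclude_rrt: bool = True

    @classmethod
    def from_config(cls, cfg: Optional[dict]) -> "ExclusionCriteria":
        return cls(**cfg) if cfg else cls()


CRITERIA_ORDER = (
    "los_le_24h",
    "missing_demographics",
    "age_over_90",
    "admission_oligoanuria",
    "rrt_during_stay",
    "insufficient_data",
)


def _admission_oligoanuric(encounter: Encounter, criteria: ExclusionCriteria) -> bool:
    """Mean weight-normalised urine output below threshold over the first
    window hours of admission, requiring full charting coverage of the
    window; encounters without that coverage are not flagged here."""
    grid = hourly_uo_rate(encounter)
    w = criteria.oligoanuria_window_hours
    if grid is None or len(grid) < w:
        return False
    first = grid.rate_per_kg[:w]
    if np.isnan(first).any():
        return False
    return float(first.mean()) < criteria.oligoanuria_rate


def _insufficient_data(encounter: Encounter) -> bool:
    """No route to any stage value: neither (urine output and weight) for a
    UO stage nor any creatinine for a Cr stage."""
    has_uo = encounter.has_any("urine_output") and encounter.has_any("weight")
    has_cr = encounter.has_any("creatinine")
    return not (has_uo or has_cr)


def apply_exclusions(
    encounters: Sequence[Encounter],
    criteria: ExclusionCriteria = ExclusionCriteria(),
) -> "tuple[list, ExclusionReport]":
    """Apply the cascade in fixed order with first-match counting."""
    counts = {name: 0 for name in CRITERIA_ORDER}
    retained = []
    for e in encounters:
        reason = exclusion_reason(e, criteria)
        if reason is None:
            retained.append(e)
        else:
            counts[reason] += 1
    report = ExclusionReport(initial=len(encounters), excluded=counts, retained=len(retained))
    return retained, report


def exclusion_reason(encounter: Encounter, criteria: ExclusionCriteria = ExclusionCriteria()) -> Optional[str]:
    """First failed criterion in cascade order, or None if retained."""
    if not encounter.los_hours > criteria.min_los_hours:
        return "los_le_24h"
    if not encounter.demographics.complete:
        return "missing_demographics"
    if encounter.demographics.age > criteria.max_age_years:
        return "age_over_90"
    if _admission_oligoanuric(encounter, criteria):
        return "admission_oligoanuria"
    if criteria.exclude_rrt and encounter.on_rrt_during_stay():
        return "rrt_during_stay"
    if _insufficient_data(encounter):
        return "insufficient_data"
    return None


def write_exclusion_report(report: ExclusionReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def write_outcomes_table(outcomes: pd.DataFrame, path) -> None:
    """Per-encounter outcomes CSV with a deterministic column order."""
    from akiflow.outcomes import OUTCOME_COLUMNS

    frame = outcomes.reindex(columns=OUTCOME_COLUMNS)
    frame.to_csv(path, index=False)
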