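"""Domain model: encounters, chart events, stage series, exclusion reports.

Chart events are held per encounter as a tidy pandas frame (``timestamp``,
``kind``, ``value``) sorted by time; stage series are step functions over
absolute timestamps with integer stage values 0-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Recognised chart-event kinds and the unit each value carries.
EVENT_KINDS = (
    "urine_output",        # mL accumulated since the previous urine charting
    "creatinine",          # mg/dL (canonical internal unit)
    "weight",              # kg
    "egfr",                # mL/min/1.73 m^2
    "enoxaparin_dose",     # mg
    "rrt_start",           # marker, value ignored
    "rrt_stop",            # marker, value ignored
    "baseline_creatinine", # mg/dL
)

SEXES = ("female", "male")
UNITS = ("GICU", "CICU")
ADMISSION_TYPES = ("medical", "surgical-emergency", "surgical-urgent", "surgical-elective")

#: 1 mg/dL of creatinine in umol/L.
UMOL_PER_MGDL = 88.42


@dataclass
class Demographics:
    """Age, sex, race and unit for one encounter.

    Fields may be None at assembly time; completeness is enforced by the
    exclusion cascade, not at construction, so that encounters with missing
    demographics can be counted rather than rejected on read.
    """

    age: Optional[float]
    sex: Optional[str]
    race_black: Optional[bool]
    unit: Optional[str]
    admission_type: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.unit is not None and self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if self.admission_type is not None and self.admission_type not in ADMISSION_TYPES:
            raise ValueError(f"unknown admission_type {self.admission_type!r}")

    @property
    def complete(self) -> bool:
        """True when age, sex and race — the fields MDRD needs — are present."""
        return self.age is not None and self.sex is not None and self.race_black is not None


@dataclass(frozen=True)
class ChartEvent:
    timestamp: pd.Timestamp
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"negative value {self.value} for {self.kind}")


def _as_event_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        frame = events.loc[:, ["timestamp", "kind", "value"]].copy()
    else:
        frame = pd.DataFrame(
            [(e.timestamp, e.kind, e.value) for e in events],
            columns=["timestamp", "kind", "value"],
        )
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame = frame.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return frame


@dataclass
class Encounter:
    """One ICU admission: demographics plus time-ordered chart-event streams."""

    encounter_id: str
    demographics: Demographics
    admission_time: pd.Timestamp
    discharge_time: pd.Timestamp
    events: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["timestamp", "kind", "value"]))
    charted_baseline_creatinine: Optional[float] = None
    rrt_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.admission_time = pd.Timestamp(self.admission_time)
        self.discharge_time = pd.Timestamp(self.discharge_time)
        if not self.discharge_time > self.admission_time:
            raise ValueError(
                f"encounter {self.encounter_id}: discharge {self.discharge_time} "
                f"not after admission {self.admission_time}"
            )
        self.events = _as_event_frame(self.events)

    @property
    def los_hours(self) -> float:
        return (self.discharge_time - self.admission_time) / pd.Timedelta(hours=1)

    def events_of(self, *kinds: str) -> pd.DataFrame:
        """Events of the given kind(s), time-sorted."""
        return self.events[self.events["kind"].isin(kinds)]

    def has_any(self, kind: str) -> bool:
        return bool((self.events["kind"] == kind).any())

    def hours_since_admission(self, timestamps: Iterable) -> np.ndarray:
        ts = pd.DatetimeIndex(timestamps)
        return ((ts - self.admission_time) / pd.Timedelta(hours=1)).to_numpy()

    def on_rrt_during_stay(self) -> bool:
        return len(self.rrt_intervals) > 0


@dataclass(frozen=True)
class StagePoint:
    timestamp: pd.Timestamp
    stage: int
    source: str  # 'uo' | 'cr' | 'combined'

    def __post_init__(self) -> None:
        if self.stage not in (0, 1, 2, 3):
            raise ValueError(f"stage must be 0-3, got {self.stage}")


class StageSeries:
    """A time-ordered AKI stage step function for one source.

    The stage holds its value from each evaluation until the next one
    ("most recent value" semantics); before the first evaluation the stage
    is undefined and `value_at` returns None.
    """

    def __init__(self, encounter_id: str, source: str, times=(), stages=()) -> None:
        self.encounter_id = encounter_id
        self.source = source
        self.times = pd.DatetimeIndex(times)
        self.stages = np.asarray(stages, dtype=int)
        if len(self.times) != len(self.stages):
            raise ValueError("times and stages length mismatch")
        if len(self.times) > 1 and (self.times[1:] < self.times[:-1]).any():
            raise ValueError("stage points must be time-sorted")
        if len(self.stages) and ((self.stages < 0) | (self.stages > 3)).any():
            raise ValueError("stages must lie in 0..3")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        for t, s in zip(self.times, self.stages):
            yield StagePoint(t, int(s), self.source)

    def value_at(self, t) -> Optional[int]:
        """Latest stage with timestamp <= t, or None before any evaluation."""
        i = self.times.searchsorted(pd.Timestamp(t), side="right")
        return int(self.stages[i - 1]) if i > 0 else None

    def max_in(self, start, end, carry_forward: bool = True) -> Optional[int]:
        """Maximum stage over [start, end); carried-in value included by default.

        The carried value only counts when it actually holds for a nonempty
        sub-interval of the window, i.e. when no point sits exactly at
        `start`.
        """
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        lo = self.times.searchsorted(start, side="left")
        hi = self.times.searchsorted(end, side="left")
        best: Optional[int] = None
        if hi > lo:
            best = int(self.stages[lo:hi].max())
        update_at_start = hi > lo and self.times[lo] == start
        if carry_forward and lo > 0 and not update_at_start:
            carried = int(self.stages[lo - 1])
            best = carried if best is None else max(best, carried)
        return best

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "encounter_id": self.encounter_id,
                "timestamp": self.times,
                "source": self.source,
                "stage": self.stages,
            }
        )

    @property
    def max_stage(self) -> int:
        return int(self.stages.max()) if len(self.stages) else 0


@dataclass
class ExclusionReport:
    """Audit trail of the exclusion cascade.

    `excluded` maps criterion name -> count, in application order; every
    encounter is counted under the first criterion it fails, so
    `initial == retained + sum(excluded.values())` always holds.
    """

    initial: int
    excluded: "dict[str, int]"
    retained: int

    def __post_init__(self) -> None:
        if self.initial != self.retained + sum(self.excluded.values()):
            raise ValueError("exclusion counts do not conserve the input size")

    def to_dict(self) -> dict:
        return {"initial": self.initial, "excluded": dict(self.excluded), "retained": self.retained}


def sort_encounters(encounters: Sequence[Encounter]) -> list:
    return sorted(encounters, key=lambda e: e.encounter_id)
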