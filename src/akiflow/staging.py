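"""Event-driven AKIN stage computation: urine-output, creatinine and combined.

The urine-output stream is resampled to an hourly weight-normalised rate
grid (each charted volume spread uniformly over the interval since the
previous charting), then trailing windows ending at each hour are tested
against the AKIN thresholds:

    stage 1:  mean rate over trailing  6 h < 0.5 mL/kg/h
    stage 2:  mean rate over trailing 12 h < 0.5 mL/kg/h
    stage 3:  mean rate over trailing 24 h < 0.3 mL/kg/h,
              or every hour of the trailing 12 h anuric (< 1 mL/h)

The creatinine stream is staged per measurement against the resolved
baseline:

    stage 1:  scr/baseline >= 1.5  or  scr - baseline >= 0.3 mg/dL
    stage 2:  scr/baseline > 2
    stage 3:  scr/baseline > 3  or  (scr >= 4.0 and rise >= 0.5)

The combined stage at any instant is the maximum of the most recent
urine-output stage and the most recent creatinine stage. Hours without
urine charting coverage invalidate every window containing them rather
than counting as zero output; stages are not ratcheted and may fall when
the physiology recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from akiflow.model import Encounter, StageSeries
from akiflow.renal import BaselineResolution


@dataclass(frozen=True)
class StagingRules:
    """AKIN thresholds and window lengths; all configurable.

    `uo_window_mode` selects how a trailing window qualifies: 'mean'
    (window-mean rate below threshold, the default) or 'all_hours' (every
    hour in the window below threshold).
    """

    uo_stage1_rate: float = 0.5     # mL/kg/h
    uo_stage1_hours: int = 6
    uo_stage2_rate: float = 0.5
    uo_stage2_hours: int = 12
    uo_stage3_rate: float = 0.3
    uo_stage3_hours: int = 24
    anuria_hours: int = 12
    anuric_ml_per_h: float = 1.0    # raw mL/h, not weight-normalised
    cr_stage1_ratio: float = 1.5    # >=
    cr_stage1_rise: float = 0.3     # mg/dL, >=
    cr_stage2_ratio: float = 2.0    # >
    cr_stage3_ratio: float = 3.0    # >
    cr_stage3_abs: float = 4.0      # mg/dL, >=
    cr_stage3_acute_rise: float = 0.5  # mg/dL, >=
    uo_window_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.uo_window_mode not in ("mean", "all_hours"):
            raise ValueError(f"unknown uo_window_mode {self.uo_window_mode!r}")
        if not (self.uo_stage1_hours < self.uo_stage2_hours < self.uo_stage3_hours):
            raise ValueError("UO windows must be strictly increasing across stages")

    @classmethod
    def from_config(cls, cfg: Optional[dict]) -> "StagingRules":
        return cls(**cfg) if cfg else cls()


DEFAULT_RULES = StagingRules()


@dataclass
class HourlyUORates:
    """Weight-normalised urine output on an hourly grid from admission.

    `rate_per_kg[h]` covers [admission + h, admission + h + 1) in mL/kg/h;
    NaN marks hours without full charting coverage or without a prior
    weight. `rate_ml[h]` is the raw un-normalised rate in mL/h (for the
    anuria criterion).
    """

    encounter_id: str
    admission_time: pd.Timestamp
    rate_per_kg: np.ndarray = field(default_factory=lambda: np.empty(0))
    rate_ml: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.rate_per_kg)


def hourly_uo_rate(encounter: Encounter) -> Optional[HourlyUORates]:
    """Resample charted urine volumes to an hourly weight-normalised grid.

    Each charted volume is spread uniformly over the interval since the
    previous urine charting (or admission for the first), so the cumulative
    volume is piecewise linear in time; hourly volumes are its differences
    at hour boundaries. Coverage is contiguous from admission to the last
    urine event; hours ending beyond it are not represented. Each hour is
    divided by the most recent weight as of the start of the hour (a weight
    charted exactly on the boundary applies to that hour); hours before the
    first weight are NaN.

    Returns None when the encounter has no urine events or no weight at
    all — urine-output staging is then uncomputable, not an error.
    """
    uo = encounter.events_of("urine_output")
    wt = encounter.events_of("weight")
    if not len(uo) or not len(wt):
        return None

    t_uo = encounter.hours_since_admission(uo["timestamp"])
    vols = uo["value"].to_numpy(dtype=float)
    # collapse duplicate charting timestamps by summing volumes
    if len(t_uo) > 1 and (np.diff(t_uo) <= 0).any():
        order = np.argsort(t_uo, kind="stable")
        t_uo, vols = t_uo[order], vols[order]
        t_uo, inv = np.unique(t_uo, return_inverse=True)
        vols = np.bincount(inv, weights=vols)
    keep = t_uo > 0  # volumes charted at/before admission have no in-stay interval
    t_uo, vols = t_uo[keep], vols[keep]
    if not len(t_uo):
        return None

    n_hours = int(np.floor(t_uo[-1]))
    if n_hours <= 0:
        return HourlyUORates(encounter.encounter_id, encounter.admission_time,
                             np.empty(0), np.empty(0))

    cum = np.concatenate([[0.0], np.cumsum(vols)])
    knots = np.concatenate([[0.0], t_uo])
    bounds = np.arange(n_hours + 1, dtype=float)
    hourly_ml = np.diff(np.interp(bounds, knots, cum))

    t_wt = encounter.hours_since_admission(wt["timestamp"])
    w_vals = wt["value"].to_numpy(dtype=float)
    order = np.argsort(t_wt, kind="stable")
    t_wt, w_vals = t_wt[order], w_vals[order]
    # weight index for each hour start; side='right' so a weight on the
    # boundary belongs to the hour that starts there
    idx = np.searchsorted(t_wt, bounds[:-1], side="right") - 1
    weight_at = np.where(idx >= 0, w_vals[np.clip(idx, 0, None)], np.nan)

    rate_per_kg = hourly_ml / weight_at
    return HourlyUORates(encounter.encounter_id, encounter.admission_time,
                         rate_per_kg, hourly_ml.astype(float))


def _trailing_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over the trailing `window` entries ending at each index; NaN
    where the window is incomplete or contains a NaN.

    Per-window summation (not a running cumsum) so that exact threshold
    boundaries are not blurred by accumulated round-off.
    """
    n = len(values)
    out = np.full(n, np.nan)
    if n < window:
        return out
    out[window - 1:] = np.lib.stride_tricks.sliding_window_view(values, window).mean(axis=1)
    return out


def _trailing_all_below(values: np.ndarray, window: int, threshold: float) -> np.ndarray:
    """True where every entry of the trailing window is < threshold (no NaN)."""
    n = len(values)
    out = np.zeros(n, dtype=bool)
    if n < window:
        return out
    ok = (values < threshold) & ~np.isnan(values)
    out[window - 1:] = np.lib.stride_tricks.sliding_window_view(ok, window).all(axis=1)
    return out


def stage_uo(grid: Optional[HourlyUORates], rules: StagingRules = DEFAULT_RULES) -> StageSeries:
    """Urine-output stage series from an hourly rate grid.

    Each hour end is an evaluation instant; a window is eligible only when
    every hour in it is non-missing; the emitted stage is the maximum
    satisfied among eligible windows. A point is recorded at the first
    eligible hour and whenever the value changes.
    """
    if grid is None or len(grid) == 0:
        return StageSeries("" if grid is None else grid.encounter_id, "uo")

    r = grid.rate_per_kg
    if rules.uo_window_mode == "mean":
        s1 = _trailing_mean(r, rules.uo_stage1_hours) < rules.uo_stage1_rate
        s2 = _trailing_mean(r, rules.uo_stage2_hours) < rules.uo_stage2_rate
        s3_olig = _trailing_mean(r, rules.uo_stage3_hours) < rules.uo_stage3_rate
    else:
        s1 = _trailing_all_below(r, rules.uo_stage1_hours, rules.uo_stage1_rate)
        s2 = _trailing_all_below(r, rules.uo_stage2_hours, rules.uo_stage2_rate)
        s3_olig = _trailing_all_below(r, rules.uo_stage3_hours, rules.uo_stage3_rate)
    s3_anuria = _trailing_all_below(grid.rate_ml, rules.anuria_hours, rules.anuric_ml_per_h)
    # NaN-aware eligibility: the stage-1 window is the shortest, so an hour
    # is evaluable iff its trailing stage-1 window is complete
    evaluable = ~np.isnan(_trailing_mean(r, rules.uo_stage1_hours))

    stage = np.zeros(len(r), dtype=int)
    stage[np.asarray(s1, bool)] = 1
    stage[np.asarray(s2, bool)] = 2
    stage[np.asarray(s3_olig, bool) | s3_anuria] = 3

    hours = np.nonzero(evaluable)[0]
    if not len(hours):
        return StageSeries(grid.encounter_id, "uo")
    values = stage[hours]
    # emit at first evaluable hour and at changes
    keep = np.concatenate([[True], values[1:] != values[:-1]])
    emit_hours, emit_vals = hours[keep], values[keep]
    times = grid.admission_time + pd.to_timedelta(emit_hours + 1, unit="h")  # hour ends
    return StageSeries(grid.encounter_id, "uo", times, emit_vals)


def cr_stage_value(scr: float, baseline: float, rules: StagingRules = DEFAULT_RULES) -> int:
    """AKIN creatinine stage for a single measurement (mg/dL)."""
    if not baseline > 0:
        raise ValueError(f"baseline creatinine must be positive, got {baseline}")
    ratio = scr / baseline
    rise = scr - baseline
    if ratio > rules.cr_stage3_ratio or (
        scr >= rules.cr_stage3_abs and rise >= rules.cr_stage3_acute_rise
    ):
        return 3
    if ratio > rules.cr_stage2_ratio:
        return 2
    if ratio >= rules.cr_stage1_ratio or rise >= rules.cr_stage1_rise:
        return 1
    return 0


def stage_cr(
    encounter: Encounter,
    baseline: BaselineResolution,
    rules: StagingRules = DEFAULT_RULES,
) -> StageSeries:
    """Creatinine stage series: one point per creatinine measurement."""
    cr = encounter.events_of("creatinine")
    if not len(cr):
        return StageSeries(encounter.encounter_id, "cr")
    stages = [cr_stage_value(v, baseline.value, rules) for v in cr["value"].to_numpy(dtype=float)]
    return StageSeries(encounter.encounter_id, "cr", pd.DatetimeIndex(cr["timestamp"]), stages)


def combined_stage(uo: StageSeries, cr: StageSeries) -> StageSeries:
    """Maximum of the most recent UO and Cr stages, evaluated at every
    instant either component updates; a component with no value yet
    contributes 0."""
    encounter_id = uo.encounter_id or cr.encounter_id
    if not len(uo) and not len(cr):
        return StageSeries(encounter_id, "combined")
    times = pd.DatetimeIndex(np.union1d(uo.times.to_numpy(), cr.times.to_numpy()))
    t = times.to_numpy()

    def latest(series: StageSeries) -> np.ndarray:
        if not len(series):
            return np.zeros(len(t), dtype=int)
        idx = np.searchsorted(series.times.to_numpy(), t, side="right") - 1
        vals = series.stages[np.clip(idx, 0, None)]
        return np.where(idx >= 0, vals, 0)

    values = np.maximum(latest(uo), latest(cr))
    return StageSeries(encounter_id, "combined", times, values)


def annotate_rrt_stage3(series: StageSeries, rrt_intervals) -> StageSeries:
    """Display overlay: pin the stage to 3 inside RRT intervals.

    A presentation convenience only — analysis cohorts exclude RRT
    encounters because dialysis invalidates both staging inputs, but a
    bedside display shows them as stage 3. Points falling inside any
    [start, stop) interval are raised to 3, and a stage-3 point is
    inserted at each interval start not already covered.
    """
    if not rrt_intervals:
        return series
    times = list(series.times)
    stages = list(series.stages)
    for start, stop in rrt_intervals:
        start, stop = pd.Timestamp(start), pd.Timestamp(stop)
        if start not in series.times:
            times.append(start)
            stages.append(3)
        for i, t in enumerate(series.times):
            if start <= t < stop:
                stages[i] = 3
    order = np.argsort(pd.DatetimeIndex(times), kind="stable")
    return StageSeries(
        series.encounter_id, series.source,
        pd.DatetimeIndex(times)[order], np.asarray(stages)[order],
    )


@dataclass
class StageBundle:
    """The three stage series for one encounter, plus computability flags."""

    encounter_id: str
    uo: StageSeries
    cr: StageSeries
    combined: StageSeries
    uo_computable: bool = True
    baseline: Optional[BaselineResolution] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.uo.to_frame(), self.cr.to_frame(), self.combined.to_frame()],
            ignore_index=True,
        )


def stage_encounter(
    encounter: Encounter,
    baseline: BaselineResolution,
    rules: StagingRules = DEFAULT_RULES,
) -> StageBundle:
    """Compute the UO, Cr and combined stage series for one encounter."""
    grid = hourly_uo_rate(encounter)
    uo = stage_uo(grid, rules)
    if not uo.encounter_id:
        uo = StageSeries(encounter.encounter_id, "uo")
    cr = stage_cr(encounter, baseline, rules)
    combined = combined_stage(uo, cr)
    return StageBundle(
        encounter_id=encounter.encounter_id,
        uo=uo,
        cr=cr,
        combined=combined,
        uo_computable=grid is not None,
        baseline=baseline,
    )
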