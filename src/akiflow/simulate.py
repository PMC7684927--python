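"""Synthetic two-ICU cohort generator with known latent AKI trajectories.

Latent stages evolve on a daily Markov-style clock per encounter: an
optional AKI onset (hazard shaped by unit type — cardiac-ICU injury is
concentrated in the first postoperative day, general-ICU onset is spread
across the stay), a Bernoulli stage-1 progression the following day, an
optional stage-2 -> 3 step, then one-stage-per-day recovery; stage 3 is
absorbing until discharge. Emissions are hourly and, in noise-free mode,
sit exactly inside the AKIN band of the latent stage, so the staging
engine recovers the latent path and the configured progression and
dosing-error rates are recoverable by the downstream modules.

Per latent stage the emitted daily profile is:

    stage 0: urine 1.0 mL/kg/h all day;      SCr = baseline
    stage 1: urine 0.4 for the first 8 h;    SCr = 1.6 x baseline
    stage 2: urine 0.4 for the first 14 h;   SCr = 2.5 x baseline
    stage 3: urine 0.25 all day;             SCr = 3.5 x baseline

with one SCr (and matching MDRD eGFR) charted at each day start, weight at
admission, and a daily enoxaparin opportunity at hour 10 whose dose is the
eGFR-recommended amount or — with the configured error probability — an
excessive one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from akiflow.enoxaparin import DEFAULT_DOSE_TABLE, recommended_dose
from akiflow.model import Demographics, Encounter
from akiflow.renal import DEFAULT_MDRD, estimate_baseline_scr, mdrd_egfr

#: SCr multiple of baseline emitted during a latent stage-k day; chosen to
#: sit strictly inside each AKIN creatinine band (1.5-2, >2-3, >3).
STAGE_SCR_RATIO = (1.0, 1.6, 2.5, 3.5)
#: (low-rate mL/kg/h, hours of low output at the start of the day)
STAGE_UO_PROFILE = {0: (1.0, 0), 1: (0.4, 8), 2: (0.4, 14), 3: (0.25, 24)}
_NORMAL_UO = 1.0  # mL/kg/h outside oliguric hours


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults emulate the control-phase cohort.

    Rates: stage-1 progression 0.42, stage-2 -> 3 progression 0.213,
    admission AKI 0.065, in-ICU onset 0.339, incorrect enoxaparin dose
    0.0172, charted baseline 0.016, RRT 0.065. Demographics and length of
    stay: age 63.6 (14.5) y, 32.1% female, 1.3% black, 41.8% general-ICU,
    LOS log-normal with mean 5.8 and SD 6.7 days. `intervention_config()`
    swaps in the after-phase rates.
    """

    n_encounters: int = 1000
    unit_gicu_fraction: float = 0.418
    female_fraction: float = 0.321
    race_black_fraction: float = 0.013
    age_mean: float = 63.6
    age_sd: float = 14.5
    age_range: "tuple[float, float]" = (18.0, 95.0)
    los_mean_days: float = 5.8
    los_sd_days: float = 6.7
    los_min_days: float = 26.0 / 24.0   # everyone stays > 24 h
    los_max_days: float = 40.0
    los_fixed_days: Optional[float] = None  # overrides the distribution (calibration runs)
    weight_mean: float = 81.0
    weight_sd: float = 20.0
    weight_range: "tuple[float, float]" = (45.0, 140.0)
    baseline_scr_sigma: float = 0.15    # log-scale spread of charted baselines
    fraction_charted_baseline: float = 0.016
    p_admission_aki: float = 0.065
    p_onset: float = 0.339              # in-ICU AKI among those not admitted with it
    p_progress_from_1: float = 0.42
    p_2_to_3: float = 0.213
    onset_day_fixed: Optional[int] = None  # force onset day (calibration runs)
    scr_noise_sd: float = 0.0           # fractional; 0 = noise-free emissions
    uo_noise_sd: float = 0.0
    uo_charting_interval_h: int = 1
    enoxaparin_dose_hour: float = 10.0
    p_dose_error: float = 0.0172
    #: probability of charting an erroneous 40 mg dose when the recommended
    #: dose is 0 (contraindicated). Off by default: correct behaviour there
    #: is to chart nothing, so any nonzero value inflates the measured
    #: incorrect fraction above p_dose_error.
    p_contraindicated_dose: float = 0.0
    rrt_probability: float = 0.065
    missing_demographics_fraction: float = 0.005

    def validate(self) -> None:
        probs = (
            self.unit_gicu_fraction, self.female_fraction, self.race_black_fraction,
            self.fraction_charted_baseline, self.p_admission_aki, self.p_onset,
            self.p_progress_from_1, self.p_2_to_3, self.p_dose_error,
            self.rrt_probability, self.missing_demographics_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_encounters < 0:
            raise ValueError("n_encounters must be >= 0")
        if self.uo_charting_interval_h < 1:
            raise ValueError("uo_charting_interval_h must be >= 1")


def control_config(**overrides) -> CohortConfig:
    """Control-phase study conditions (the dataclass defaults)."""
    return replace(CohortConfig(), **overrides)


def intervention_config(**overrides) -> CohortConfig:
    """After-phase study conditions: lower progression and dosing-error
    rates, baseline creatinine mostly charted."""
    base = CohortConfig(
        fraction_charted_baseline=0.58,
        p_onset=0.29,
        p_progress_from_1=0.335,
        p_2_to_3=0.118,
        p_dose_error=0.006,
        rrt_probability=0.079,
    )
    return replace(base, **overrides)


@dataclass
class LatentTruth:
    """Ground truth behind a generated cohort.

    `table` has one row per encounter (max stage, progression flags, first
    AKI day, injected dose errors, exclusion-relevant flags);
    `stage_paths` maps encounter_id -> daily latent stage array.
    """

    table: pd.DataFrame
    stage_paths: "dict[str, np.ndarray]" = field(default_factory=dict)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def _lognormal_los(rng, cfg: CohortConfig, size: int) -> np.ndarray:
    if cfg.los_fixed_days is not None:
        return np.full(size, float(cfg.los_fixed_days))
    cv2 = (cfg.los_sd_days / cfg.los_mean_days) ** 2
    sigma = math.sqrt(math.log1p(cv2))
    mu = math.log(cfg.los_mean_days) - 0.5 * sigma**2
    los = rng.lognormal(mu, sigma, size=size)
    return np.clip(los, cfg.los_min_days, cfg.los_max_days)


def _sample_onset_day(rng, unit: str, n_days: int, last_allowed: int,
                      fixed: Optional[int]) -> Optional[int]:
    """AKI onset day >= 2; cardiac-ICU hazard is front-loaded (postoperative
    injury in the first day or two), general-ICU hazard is flat."""
    if fixed is not None:
        return fixed if 2 <= fixed <= last_allowed else None
    if last_allowed < 2:
        return None
    days = np.arange(2, last_allowed + 1)
    if unit == "CICU":
        weights = np.exp(-(days - 2) / 1.0)   # concentrated on day 2
    else:
        weights = np.exp(-(days - 2) / 6.0)   # progressive insult, spread out
    return int(rng.choice(days, p=weights / weights.sum()))


def _latent_path(rng, cfg: CohortConfig, unit: str, n_days: int) -> np.ndarray:
    """Daily latent stage trajectory for one encounter.

    Onset to stage 1 (or stage 1 from day 1 for admission AKI), Bernoulli
    progression to stage 2 the next day, optional 2 -> 3 the day after,
    one-stage-per-day recovery; stage 3 is absorbing until discharge.
    """
    path = np.zeros(n_days, dtype=int)
    admitted_with = rng.random() < cfg.p_admission_aki
    if admitted_with:
        onset = 1
    elif rng.random() < cfg.p_onset:
        onset = _sample_onset_day(rng, unit, n_days, n_days - 1, cfg.onset_day_fixed)
        if onset is None:
            return path
    else:
        return path

    progress = rng.random() < cfg.p_progress_from_1
    d = onset - 1                      # 0-based index of the stage-1 day
    path[d] = 1
    peak_idx = d
    if progress and d + 1 < n_days:
        path[d + 1] = 2
        peak_idx = d + 1
        if rng.random() < cfg.p_2_to_3 and d + 2 < n_days:
            path[d + 2 :] = 3          # absorbing
            return path
    # step-down recovery from the peak
    stage = path[peak_idx]
    i = peak_idx + 1
    while stage > 1 and i < n_days:
        stage -= 1
        path[i] = stage
        i += 1
    return path


def _hourly_uo_per_kg(path: np.ndarray, n_hours: int, admission_aki: bool) -> np.ndarray:
    rates = np.full(n_hours, _NORMAL_UO)
    for day, stage in enumerate(path):
        lo, hi = 24 * day, min(24 * (day + 1), n_hours)
        if hi <= lo:
            break
        if day == 0 and admission_aki:
            # community-acquired AKI presents through creatinine; urine
            # output stays normal on the admission day so these encounters
            # are not swept up by the admission-oligoanuria exclusion
            continue
        low_rate, low_hours = STAGE_UO_PROFILE[int(stage)]
        cut = min(lo + low_hours, hi)
        rates[lo:cut] = low_rate
        # remaining hours of the day stay at the normal rate
    return rates


def _generate_encounter(rng, cfg: CohortConfig, index: int, base_time: pd.Timestamp,
                        mdrd=DEFAULT_MDRD):
    eid = f"enc{index:05d}"
    unit = "GICU" if rng.random() < cfg.unit_gicu_fraction else "CICU"
    female = rng.random() < cfg.female_fraction
    black = rng.random() < cfg.race_black_fraction
    age = float(_truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range))
    weight = float(_truncated_normal(rng, cfg.weight_mean, cfg.weight_sd, *cfg.weight_range))
    los_hours = float(_lognormal_los(rng, cfg, 1)[0] * 24.0)
    n_days = math.ceil(los_hours / 24.0)
    missing_demo = rng.random() < cfg.missing_demographics_fraction
    on_rrt = rng.random() < cfg.rrt_probability
    charted_baseline = rng.random() < cfg.fraction_charted_baseline

    # The engine resolves uncharted baselines by MDRD back-calculation; the
    # latent baseline matches that resolution so noise-free emissions stage
    # exactly. Charted baselines carry individual log-normal variation.
    mdrd_baseline = estimate_baseline_scr(age, female, black, params=mdrd)
    if charted_baseline:
        baseline_scr = float(mdrd_baseline * rng.lognormal(0.0, cfg.baseline_scr_sigma))
    else:
        baseline_scr = mdrd_baseline

    path = _latent_path(rng, cfg, unit, n_days)
    admission = base_time + pd.Timedelta(minutes=7 * index)
    discharge = admission + pd.Timedelta(hours=los_hours)

    n_hours = int(math.floor(los_hours))
    admission_aki = bool(len(path) and path[0] >= 1)
    rate_per_kg = _hourly_uo_per_kg(path, n_hours, admission_aki)
    if cfg.uo_noise_sd > 0:
        rate_per_kg = rate_per_kg * np.clip(
            1.0 + rng.normal(0.0, cfg.uo_noise_sd, size=n_hours), 0.05, None
        )

    times, kinds, values = [], [], []

    def emit(hour: float, kind: str, value: float) -> None:
        times.append(hour)
        kinds.append(kind)
        values.append(value)

    emit(0.0, "weight", weight)
    if charted_baseline:
        emit(0.0, "baseline_creatinine", baseline_scr)

    step = cfg.uo_charting_interval_h
    for h_end in range(step, n_hours + 1, step):
        vol = float(rate_per_kg[h_end - step : h_end].sum()) * weight
        emit(float(h_end), "urine_output", vol)

    n_doses = n_dose_errors = 0
    for day in range(n_days):
        day_h = 24.0 * day
        if day_h >= los_hours:
            break
        stage = int(path[day])
        scr = baseline_scr * STAGE_SCR_RATIO[stage]
        if cfg.scr_noise_sd > 0:
            scr *= max(0.05, 1.0 + rng.normal(0.0, cfg.scr_noise_sd))
        emit(day_h, "creatinine", scr)
        egfr = mdrd_egfr(scr, age, female, black, params=mdrd)
        emit(day_h, "egfr", egfr)

        dose_h = day_h + cfg.enoxaparin_dose_hour
        if dose_h < los_hours:
            rec = recommended_dose(egfr, DEFAULT_DOSE_TABLE)
            if rec > 0:
                # every opportunity charts exactly one dose, wrong with
                # probability p_dose_error -> the measured incorrect
                # fraction is exactly Binomial(p_dose_error)
                if rng.random() < cfg.p_dose_error:
                    # missed renal adjustment (40 instead of 20) or
                    # therapeutic-dose confusion (80 instead of 40)
                    emit(dose_h, "enoxaparin_dose", 40.0 if rec < 40.0 else 2.0 * rec)
                    n_dose_errors += 1
                else:
                    emit(dose_h, "enoxaparin_dose", rec)
                n_doses += 1
            elif rng.random() < cfg.p_contraindicated_dose:
                emit(dose_h, "enoxaparin_dose", 40.0)
                n_doses += 1
                n_dose_errors += 1

    rrt_window = None
    if on_rrt:
        rrt_start = min(24.0, los_hours / 2.0)
        rrt_stop = min(rrt_start + 24.0, los_hours)
        emit(rrt_start, "rrt_start", 0.0)
        emit(rrt_stop, "rrt_stop", 0.0)
        rrt_window = (rrt_start, rrt_stop)

    # chart at 1-minute resolution (floor, so nothing lands past discharge)
    minutes = np.floor(np.asarray(times) * 60.0)
    events = pd.DataFrame(
        {
            "timestamp": admission + pd.to_timedelta(minutes, unit="m"),
            "kind": kinds,
            "value": values,
        }
    )
    demo = Demographics(
        age=age,
        sex=None if missing_demo else ("female" if female else "male"),
        race_black=None if missing_demo else black,
        unit=unit,
        admission_type="surgical-elective" if unit == "CICU" else "medical",
    )
    encounter = Encounter(
        encounter_id=eid,
        demographics=demo,
        admission_time=admission,
        discharge_time=discharge,
        events=events,
        charted_baseline_creatinine=baseline_scr if charted_baseline else None,
    )
    if rrt_window is not None:
        encounter.rrt_intervals = [
            tuple(admission + pd.Timedelta(minutes=np.floor(h * 60.0)) for h in rrt_window)
        ]

    nz = np.nonzero(path > 0)[0]
    truth_row = {
        "encounter_id": eid,
        "unit": unit,
        "n_days": n_days,
        "los_hours": los_hours,
        "max_stage": int(path.max()) if len(path) else 0,
        "admission_aki": bool(len(path) and path[0] >= 1),
        "reached_stage_1": bool((path == 1).any()),
        "progressed_from_1": bool(((path[:-1] == 1) & (path[1:] > 1)).any()) if len(path) > 1 else False,
        "progressed_2_to_3": bool(((path[:-1] == 2) & (path[1:] == 3)).any()) if len(path) > 1 else False,
        "first_aki_day": int(nz[0]) + 1 if len(nz) else None,
        "n_doses": n_doses,
        "n_dose_errors": n_dose_errors,
        "rrt": on_rrt,
        "missing_demographics": missing_demo,
        "charted_baseline": charted_baseline,
        "baseline_scr": baseline_scr,
    }
    return encounter, truth_row, path


def generate_cohort(config: CohortConfig, seed: int) -> "tuple[list, LatentTruth]":
    """Generate a cohort of encounters plus its latent ground truth.

    Deterministic under (config, seed); encounters are writable/readable
    with `akiflow.io` unchanged.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    base_time = pd.Timestamp("2023-01-01 00:00")
    encounters, rows, paths = [], [], {}
    for i in range(config.n_encounters):
        enc, row, path = _generate_encounter(rng, config, i, base_time)
        encounters.append(enc)
        rows.append(row)
        paths[enc.encounter_id] = path
    columns = [
        "encounter_id", "unit", "n_days", "los_hours", "max_stage", "admission_aki",
        "reached_stage_1", "progressed_from_1", "progressed_2_to_3", "first_aki_day",
        "n_doses", "n_dose_errors", "rrt", "missing_demographics", "charted_baseline",
        "baseline_scr",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return encounters, LatentTruth(table=table, stage_paths=paths)


def generate_two_phase_study(
    control: CohortConfig,
    intervention: CohortConfig,
    master_seed: int,
) -> dict:
    """Generate tagged control and intervention cohorts with independent
    child seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    enc_a, truth_a = generate_cohort(control, seed_a)
    enc_b, truth_b = generate_cohort(intervention, seed_b)
    return {
        "control": {"encounters": enc_a, "truth": truth_a, "seed": seed_a},
        "intervention": {"encounters": enc_b, "truth": truth_b, "seed": seed_b},
    }
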