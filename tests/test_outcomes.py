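"""Encounter outcomes, daily maxima, progression flags, KM curve, cohort table."""

import numpy as np
import pandas as pd
import pytest

from akiflow.model import StageSeries
from akiflow.outcomes import (
    EncounterOutcomes,
    admission_stage,
    cohort_outcome_table,
    compute_outcomes,
    discharge_stage,
    first_aki_day,
    km_no_aki,
    max_stage_per_day,
    progression_flags,
    proportion_pct,
)
from conftest import T0, make_encounter
from _oracles import product_limit_oracle


def series(points):  # [(hour, stage), ...]
    return StageSeries(
        "e", "combined",
        [T0 + pd.Timedelta(hours=h) for h, _ in points],
        [s for _, s in points],
    )


def outcome(first_day, discharge_day, admission=0, eid="x"):
    """Minimal outcomes record for KM tests."""
    return EncounterOutcomes(
        encounter_id=eid, admission_stage=admission, discharge_stage=0,
        max_stage=0 if first_day is None else 1, max_stage_by_day=[],
        progressed_from_1=False, progressed_2_to_3=False,
        reached_stage_1=first_day is not None, reached_stage_2=False,
        first_aki_day=first_day, discharge_day=discharge_day,
    )


# ---------------------------------------------------------------------------
# admission / discharge stage


def test_admission_stage_within_window():
    assert admission_stage(series([(3, 1), (8, 2)]), T0) == 1
    assert admission_stage(series([(2, 0)]), T0) == 0


def test_admission_stage_unknown_after_window():
    assert admission_stage(series([(7, 1)]), T0) is None
    assert admission_stage(series([]), T0) is None


def test_discharge_stage_at_last_measurement():
    enc = make_encounter(
        [(0, "weight", 80.0), (1, "creatinine", 2.5), (30, "creatinine", 1.0)],
        los_hours=48,
    )
    s = series([(1, 2), (30, 0)])
    assert discharge_stage(s, enc) == 0
    enc_single = make_encounter([(1, "creatinine", 2.5)])
    assert discharge_stage(series([(1, 2)]), enc_single) == 2


# ---------------------------------------------------------------------------
# daily maxima


def test_day_windows_with_carry_forward():
    """Stage 2 reached on day 3 carries into day 4 until re-evaluated."""
    s = series([(1, 0), (50, 2), (100, 0)])
    days = max_stage_per_day(s, T0, T0 + pd.Timedelta(hours=120), n_days=5)
    # the stage-2 state persists from hour 50 until hour 100, so it also
    # heads day 5 before the recovery evaluation
    assert days == [0, 0, 2, 2, 2]


def test_days_after_discharge_absent():
    s = series([(1, 1)])
    days = max_stage_per_day(s, T0, T0 + pd.Timedelta(hours=30), n_days=5)
    assert days[0] == 1 and days[1] == 1  # partial day 2 still reported
    assert days[2:] == [None, None, None]


def test_update_on_day_boundary_replaces_carry():
    """An evaluation exactly at a day start overrides the carried value."""
    s = series([(10, 2), (24, 0)])
    days = max_stage_per_day(s, T0, T0 + pd.Timedelta(hours=72), n_days=3)
    assert days == [2, 0, 0]


def test_events_only_mode():
    s = series([(1, 0), (50, 2)])
    days = max_stage_per_day(
        s, T0, T0 + pd.Timedelta(hours=120), n_days=5, carry_forward=False
    )
    assert days == [0, 0, 2, 0, 0]


# ---------------------------------------------------------------------------
# progression and first AKI day


@pytest.mark.parametrize(
    "stages, expected",
    [
        ([0, 1, 2], (True, False)),
        ([0, 1, 0, 1, 3], (True, False)),   # 1 -> 3 counts as "from stage 1"
        ([0, 2, 3], (False, True)),
        ([0, 1, 2, 3], (True, True)),
        ([0, 1, 1, 0], (False, False)),
        ([3, 2, 1, 0], (False, False)),     # recovery never counts
        ([1], (False, False)),
    ],
)
def test_progression_flags(stages, expected):
    pts = [(i + 1, s) for i, s in enumerate(stages)]
    assert progression_flags(series(pts)) == expected


def test_first_aki_day_day_convention():
    assert first_aki_day(series([(5, 0), (30, 1)]), T0) == 2
    assert first_aki_day(series([(24, 1)]), T0) == 2  # boundary -> the day starting there
    assert first_aki_day(series([(2, 1)]), T0) == 1
    assert first_aki_day(series([(5, 0)]), T0) is None


def test_max_stage_dominates_all_views():
    enc = make_encounter([(0, "weight", 80.0), (1, "creatinine", 1.0)], los_hours=96)
    from akiflow.renal import BaselineResolution
    from akiflow.staging import stage_encounter

    bundle = stage_encounter(enc, BaselineResolution(1.0, "charted"))
    o = compute_outcomes(enc, bundle)
    views = [d for d in o.max_stage_by_day if d is not None]
    if o.admission_stage is not None:
        views.append(o.admission_stage)
    if o.discharge_stage is not None:
        views.append(o.discharge_stage)
    assert all(o.max_stage >= v for v in views)


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_events_stays_at_one():
    outs = [outcome(None, 5) for _ in range(8)]
    km = km_no_aki(outs, max_day=5)
    np.testing.assert_allclose(km.survival, 1.0)


def test_km_all_events_day_one():
    outs = [outcome(1, 5) for _ in range(6)]
    km = km_no_aki(outs, max_day=3)
    assert km.survival[0] == 0.0


def test_km_hand_computed_table():
    """Ten encounters with mixed events/censoring match the hand-worked
    product-limit values."""
    cases = [(1, 5), (1, 5), (2, 5), (None, 2), (3, 5),
            (None, 3), (None, 5), (4, 5), (None, 4), (2, 5)]
    outs = [outcome(e, c, eid=str(i)) for i, (e, c) in enumerate(cases)]
    km = km_no_aki(outs, max_day=5)
    np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.48, 0.32, 0.32])
    assert list(km.n_at_risk) == [10, 8, 5, 3, 1]


def test_km_matches_counting_oracle(rng):
    events, censors = [], []
    for _ in range(200):
        e = int(rng.integers(1, 12)) if rng.random() < 0.5 else None
        c = int(rng.integers(1, 15))
        if e is not None and e > c:
            e = None
        events.append(e)
        censors.append(c)
    outs = [outcome(e, c, eid=str(i)) for i, (e, c) in enumerate(zip(events, censors))]
    km = km_no_aki(outs, max_day=10)
    np.testing.assert_allclose(km.survival, product_limit_oracle(events, censors, 10))


def test_km_matches_lifelines():
    """Cross-check the discrete product-limit against an established
    survival package on tied daily data."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    events, censors = [], []
    for _ in range(300):
        e = int(rng.integers(1, 9)) if rng.random() < 0.4 else None
        c = int(rng.integers(1, 12))
        if e is not None and e > c:
            e = None
        events.append(e)
        censors.append(c)
    outs = [outcome(e, c, eid=str(i)) for i, (e, c) in enumerate(zip(events, censors))]
    km = km_no_aki(outs, max_day=8)
    durations = [e if e is not None else c for e, c in zip(events, censors)]
    observed = [e is not None for e in events]
    kmf = lifelines.KaplanMeierFitter().fit(durations, observed)
    for day, s in zip(km.day, km.survival):
        assert s == pytest.approx(float(kmf.predict(day)), abs=1e-12)


def test_km_no_censoring_equals_empirical_fraction():
    cases = [(1, 10), (2, 10), (2, 10), (None, 10), (None, 10)]
    outs = [outcome(e, c, eid=str(i)) for i, (e, c) in enumerate(cases)]
    km = km_no_aki(outs, max_day=5)
    np.testing.assert_allclose(km.survival, [4 / 5, 2 / 5, 2 / 5, 2 / 5, 2 / 5])


def test_km_monotone_on_synthetic(small_cohort):
    from akiflow.io import apply_exclusions
    from akiflow.pipeline import stage_cohort

    encounters, _ = small_cohort
    retained, _ = apply_exclusions(encounters)
    _, outs = stage_cohort(retained)
    km = km_no_aki(outs)
    assert (np.diff(km.survival) <= 1e-12).all()
    assert (np.diff(km.n_at_risk) <= 0).all()


# ---------------------------------------------------------------------------
# cohort table


def test_cohort_table_counts_and_denominators():
    outs = [
        outcome(None, 5, admission=0, eid="a"),           # never AKI
        outcome(1, 5, admission=1, eid="b"),              # admitted with AKI
        outcome(2, 5, admission=0, eid="c"),              # developed in ICU
        outcome(3, 5, admission=None, eid="d"),           # unknown admission
    ]
    outs[2].max_stage = 2
    outs[3].max_stage = 1
    t = cohort_outcome_table(outs)
    assert t.n == 4 and t.admitted_with_aki == 1 and t.admission_stage_unknown == 1
    # unknown admission counts toward "not admitted with AKI"
    assert t.developed_aki_in_icu == 2
    assert t.n_not_admitted_with_aki == 3


def test_proportion_pct_absent_for_empty_denominator():
    assert proportion_pct(5, 0) is None
    t = cohort_outcome_table([])
    assert t.n == 0 and t.developed_aki_pct() is None
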