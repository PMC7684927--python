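"""Staging engine: hourly resampling, window rules, combined series."""

import numpy as np
import pandas as pd
import pytest

from akiflow.model import StageSeries
from akiflow.renal import BaselineResolution
from akiflow.staging import (
    HourlyUORates,
    StagingRules,
    combined_stage,
    cr_stage_value,
    hourly_uo_rate,
    stage_cr,
    stage_encounter,
    stage_uo,
)
from conftest import T0, hourly_uo_events, make_encounter
from _oracles import brute_force_uo_stages

BASELINE = BaselineResolution(1.0, "charted")


def grid(per_kg, weight=80.0):
    per_kg = np.asarray(per_kg, dtype=float)
    return HourlyUORates("g", T0, per_kg, per_kg * weight)


def series_hourly(series: StageSeries, n_hours: int) -> np.ndarray:
    """Expand an emitted stage series back to values at each hour end; -1
    before the first evaluation."""
    out = np.full(n_hours, -1)
    for h in range(n_hours):
        v = series.value_at(T0 + pd.Timedelta(hours=h + 1))
        if v is not None:
            out[h] = v
    return out


# ---------------------------------------------------------------------------
# hourly_uo_rate


def test_uniform_spreading_over_interval():
    """240 mL charted once after 6 h spreads to 6 hours at 0.5 mL/kg/h."""
    enc = make_encounter([(0, "weight", 80.0), (6, "urine_output", 240.0)])
    g = hourly_uo_rate(enc)
    assert len(g) == 6
    np.testing.assert_allclose(g.rate_per_kg, 0.5)
    np.testing.assert_allclose(g.rate_ml, 40.0)


def test_rate_uses_most_recent_weight():
    events = [(0, "weight", 80.0), (3, "weight", 100.0)]
    events += [(h, "urine_output", 50.0) for h in range(1, 7)]
    g = hourly_uo_rate(make_encounter(events))
    np.testing.assert_allclose(g.rate_per_kg[:3], 50.0 / 80.0)
    np.testing.assert_allclose(g.rate_per_kg[3:], 50.0 / 100.0)


def test_grid_stops_at_last_charting():
    """Hours past the last urine event carry no fabricated zeros."""
    enc = make_encounter([(0, "weight", 80.0), (4, "urine_output", 160.0)], los_hours=48)
    g = hourly_uo_rate(enc)
    assert len(g) == 4  # nothing represented beyond the covered interval


def test_no_weight_or_no_urine_is_uncomputable():
    assert hourly_uo_rate(make_encounter([(1, "urine_output", 100.0)])) is None
    assert hourly_uo_rate(make_encounter([(0, "weight", 80.0)])) is None


def test_hours_before_first_weight_are_missing():
    events = [(3, "weight", 80.0)] + [(h, "urine_output", 80.0) for h in range(1, 7)]
    g = hourly_uo_rate(make_encounter(events))
    assert np.isnan(g.rate_per_kg[:3]).all()
    assert np.isfinite(g.rate_per_kg[3:]).all()


# ---------------------------------------------------------------------------
# stage_uo


def test_stage1_fires_after_six_low_hours():
    """0.4 mL/kg/h for 7 h then normal: stage 1 appears exactly when the
    trailing 6 h mean first drops below 0.5."""
    rates = [0.4] * 7 + [0.6] * 17
    s = stage_uo(grid(rates))
    hourly = series_hourly(s, 24)
    assert hourly[5] == 1  # hours 0-5 all low -> first evaluation already 1
    assert (hourly[5:7] == 1).all()


def test_stage1_exact_boundary_from_spread_volumes():
    """A trailing-6h mean of exactly 0.5 does not stage (strict <)."""
    s = stage_uo(grid([0.5] * 12))
    assert series_hourly(s, 12)[5:].max() == 0


def test_anuria_twelve_zero_hours_is_stage3():
    rates = [1.0] * 4 + [0.0] * 12 + [1.0] * 4
    s = stage_uo(grid(rates))
    hourly = series_hourly(s, 20)
    assert hourly[15] == 3  # 12th consecutive anuric hour
    assert hourly.max() == 3


def test_normal_output_never_stages():
    s = stage_uo(grid([0.8] * 48))
    assert series_hourly(s, 48)[5:].max() == 0


def test_missing_hours_invalidate_windows():
    rates = [0.0] * 5 + [np.nan] + [0.0] * 5
    s = stage_uo(grid(rates))
    # no window of 6 complete hours exists -> no evaluation at all
    assert len(s) == 0


def test_all_hours_mode_is_stricter_than_mean():
    # one normal hour inside an otherwise oliguric stretch
    rates = [0.2] * 3 + [1.5] + [0.2] * 8
    mean_series = stage_uo(grid(rates))
    strict_series = stage_uo(grid(rates), StagingRules(uo_window_mode="all_hours"))
    h_mean = series_hourly(mean_series, 12)
    h_strict = series_hourly(strict_series, 12)
    valid = h_mean >= 0
    assert (h_strict[valid] <= h_mean[valid]).all()
    # the normal hour pulls the mean below threshold only while it is in
    # the window; the all-hours rule waits until six all-low hours exist
    assert h_mean[5] == 1 and h_strict[5] == 0 and h_strict[9] == 1


def test_uo_oracle_agreement_on_random_grids(rng):
    """Window scan matches explicit enumeration on random 72 h grids with
    gaps, anuric runs and oliguric runs."""
    for _ in range(100):
        rates = rng.exponential(0.7, size=72)
        for _ in range(rng.integers(0, 4)):  # oliguric / anuric runs
            start = int(rng.integers(0, 60))
            length = int(rng.integers(3, 30))
            rates[start : start + length] = rng.choice([0.0, 0.005, 0.2, 0.4])
        for _ in range(rng.integers(0, 3)):  # charting gaps
            start = int(rng.integers(0, 66))
            rates[start : start + int(rng.integers(1, 6))] = np.nan
        g = grid(rates)
        expected = brute_force_uo_stages(g.rate_per_kg, g.rate_ml)
        got = series_hourly(stage_uo(g), 72)
        mask = expected >= 0
        np.testing.assert_array_equal(got[mask], expected[mask])


def test_uo_monotone_in_volume(rng):
    """Scaling all volumes up never raises any stage."""
    for _ in range(25):
        rates = rng.exponential(0.5, size=48)
        lo = series_hourly(stage_uo(grid(rates)), 48)
        hi = series_hourly(stage_uo(grid(rates * 1.7)), 48)
        mask = (lo >= 0) & (hi >= 0)
        assert (hi[mask] <= lo[mask]).all()


# ---------------------------------------------------------------------------
# stage_cr


@pytest.mark.parametrize(
    "scr, baseline, expected",
    [
        (1.6, 1.0, 1),   # ratio 1.6 >= 1.5
        (0.71, 0.4, 1),  # absolute rise 0.31 >= 0.3 (ratio 1.775 too)
        (1.0, 1.0, 0),
        (2.0, 1.0, 1),   # ratio exactly 2 -> still stage 1 (stage 2 needs > 2)
        (2.01, 1.0, 2),
        (3.0, 1.0, 2),   # ratio exactly 3 -> stage 2 (stage 3 needs > 3)
        (3.3, 1.0, 3),
        (4.2, 3.5, 3),   # scr >= 4.0 with acute rise >= 0.5
        (4.2, 4.0, 0),   # scr >= 4.0 but rise 0.2: no acute component
        (1.29, 1.0, 0),  # rise 0.29 just under the absolute trigger
        (1.3, 1.0, 1),
    ],
)
def test_cr_stage_rule_table(scr, baseline, expected):
    assert cr_stage_value(scr, baseline) == expected


def test_cr_monotone_in_rise(rng):
    """Adding a positive constant to every creatinine never lowers a stage."""
    for _ in range(50):
        baseline = float(rng.uniform(0.5, 1.5))
        scr = float(rng.uniform(0.5, 5.0))
        assert cr_stage_value(scr + 0.4, baseline) >= cr_stage_value(scr, baseline)


def test_cr_stage_not_ratcheted():
    enc = make_encounter(
        [(1, "creatinine", 2.5), (10, "creatinine", 1.0)], baseline=1.0
    )
    s = stage_cr(enc, BASELINE)
    assert list(s.stages) == [2, 0]


def test_cr_requires_positive_baseline():
    with pytest.raises(ValueError):
        cr_stage_value(1.0, 0.0)


# ---------------------------------------------------------------------------
# combined


def test_combined_is_max_of_most_recent():
    uo = StageSeries("e", "uo", [T0 + pd.Timedelta(hours=1)], [1])
    cr = StageSeries("e", "cr", [T0 + pd.Timedelta(hours=2)], [2])
    c = combined_stage(uo, cr)
    assert list(c.stages) == [1, 2]


def test_combined_holds_other_component_on_drop():
    uo = StageSeries("e", "uo", [T0 + pd.Timedelta(hours=1)], [1])
    cr = StageSeries(
        "e", "cr",
        [T0 + pd.Timedelta(hours=2), T0 + pd.Timedelta(hours=3)],
        [2, 0],
    )
    c = combined_stage(uo, cr)
    assert list(c.stages) == [1, 2, 1]


def test_combined_with_empty_component_equals_other():
    uo = StageSeries("e", "uo", [T0, T0 + pd.Timedelta(hours=5)], [1, 0])
    c = combined_stage(uo, StageSeries("e", "cr"))
    assert list(c.stages) == list(uo.stages)
    assert combined_stage(StageSeries("e", "uo"), StageSeries("e", "cr")).times.empty


def test_combined_dominance(rng):
    """At every evaluation the combined stage >= each component's latest
    value and equals one of them."""
    for _ in range(50):
        t_uo = np.sort(rng.choice(np.arange(1, 73), size=8, replace=False))
        t_cr = np.sort(rng.choice(np.arange(1, 73), size=5, replace=False))
        uo = StageSeries("e", "uo", [T0 + pd.Timedelta(hours=int(h)) for h in t_uo],
                         rng.integers(0, 4, size=8))
        cr = StageSeries("e", "cr", [T0 + pd.Timedelta(hours=int(h)) for h in t_cr],
                         rng.integers(0, 4, size=5))
        c = combined_stage(uo, cr)
        for t, s in zip(c.times, c.stages):
            u, k = uo.value_at(t) or 0, cr.value_at(t) or 0
            assert s == max(u, k)


# ---------------------------------------------------------------------------
# stage_encounter


def test_creatinine_only_encounter():
    enc = make_encounter([(2, "creatinine", 1.8), (20, "creatinine", 1.0)], baseline=1.0)
    bundle = stage_encounter(enc, BASELINE)
    assert not bundle.uo_computable
    assert len(bundle.uo) == 0
    assert list(bundle.combined.stages) == list(bundle.cr.stages)


def test_healthy_trajectory_all_zero():
    events = hourly_uo_events([1.2] * 48) + [(h, "creatinine", 1.0) for h in (0, 24)]
    bundle = stage_encounter(make_encounter(events), BASELINE)
    assert bundle.combined.max_stage == 0


def test_injected_stage2_episode_recovered():
    """14 h of 0.4 mL/kg/h yields a combined stage >= 2 interval."""
    rates = [1.0] * 10 + [0.4] * 14 + [1.0] * 24
    bundle = stage_encounter(make_encounter(hourly_uo_events(rates)), BASELINE)
    assert bundle.combined.max_stage == 2


def test_rrt_annotation_overlays_stage3():
    from akiflow.staging import annotate_rrt_stage3

    s = StageSeries("e", "combined",
                    [T0 + pd.Timedelta(hours=h) for h in (2, 10, 30)], [0, 1, 0])
    out = annotate_rrt_stage3(s, [(T0 + pd.Timedelta(hours=8), T0 + pd.Timedelta(hours=20))])
    hours = [(t - T0) / pd.Timedelta(hours=1) for t in out.times]
    assert hours == [2, 8, 10, 30]
    assert list(out.stages) == [0, 3, 3, 0]
    # no intervals -> unchanged object contents
    same = annotate_rrt_stage3(s, [])
    assert list(same.stages) == [0, 1, 0]
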