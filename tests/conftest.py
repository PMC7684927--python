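import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from akiflow.model import Demographics, Encounter

T0 = pd.Timestamp("2023-03-01 08:00")


def make_encounter(
    events=None,
    los_hours=72.0,
    age=60.0,
    sex="male",
    race_black=False,
    unit="GICU",
    encounter_id="e1",
    baseline=None,
):
    """Hand-built encounter from (hour, kind, value) triples."""
    rows = [
        {"timestamp": T0 + pd.Timedelta(hours=h), "kind": k, "value": v}
        for h, k, v in (events or [])
    ]
    return Encounter(
        encounter_id=encounter_id,
        demographics=Demographics(age=age, sex=sex, race_black=race_black, unit=unit),
        admission_time=T0,
        discharge_time=T0 + pd.Timedelta(hours=los_hours),
        events=pd.DataFrame(rows, columns=["timestamp", "kind", "value"]),
        charted_baseline_creatinine=baseline,
    )


def hourly_uo_events(rates_per_kg, weight=80.0, start_hour=1):
    """Hourly urine chartings realising the given per-kg rates, plus the
    admission weight."""
    events = [(0.0, "weight", weight)]
    for i, r in enumerate(rates_per_kg):
        events.append((float(start_hour + i), "urine_output", float(r) * weight))
    return events


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230301)


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic synthetic cohort shared across tests."""
    from akiflow.simulate import CohortConfig, generate_cohort

    cfg = CohortConfig(n_encounters=60)
    return generate_cohort(cfg, seed=42)
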