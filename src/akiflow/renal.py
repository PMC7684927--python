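"""MDRD eGFR and baseline-creatinine back-calculation.

When no baseline serum creatinine is charted for an encounter, the
pre-illness baseline is estimated by inverting the 4-variable re-expressed
MDRD equation at an assumed-normal eGFR (default 75 mL/min/1.73 m^2, the
established convention for back-calculation):

    eGFR = 175 * SCr^-1.154 * age^-0.203 * 0.742[female] * 1.212[black]

All creatinine values are mg/dL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from akiflow.model import Encounter


@dataclass(frozen=True)
class MDRDParams:
    """Constants of the MDRD equation and the back-calculation convention.

    coefficient 175 corresponds to IDMS-aligned creatinine assays (the
    re-expressed equation); 186 is the original. The race coefficient can be
    disabled for cohorts where it is not recorded or not wanted.
    """

    coefficient: float = 175.0
    scr_exponent: float = -1.154
    age_exponent: float = -0.203
    female_factor: float = 0.742
    black_factor: float = 1.212
    assumed_normal_egfr: float = 75.0
    use_race_coefficient: bool = True


DEFAULT_MDRD = MDRDParams()


@dataclass(frozen=True)
class BaselineResolution:
    """A resolved baseline creatinine and where it came from."""

    value: float                      # mg/dL
    source: str                       # 'charted' | 'mdrd_estimated'
    assumed_egfr: Optional[float] = None  # set iff source == 'mdrd_estimated'

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"baseline creatinine must be positive, got {self.value}")
        if self.source not in ("charted", "mdrd_estimated"):
            raise ValueError(f"unknown baseline source {self.source!r}")


def mdrd_egfr(
    scr: float,
    age: float,
    female: bool,
    black: bool,
    params: MDRDParams = DEFAULT_MDRD,
) -> float:
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine in mg/dL."""
    if not scr > 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    if not age > 0:
        raise ValueError(f"age must be positive, got {age}")
    egfr = params.coefficient * scr ** params.scr_exponent * age ** params.age_exponent
    if female:
        egfr *= params.female_factor
    if black and params.use_race_coefficient:
        egfr *= params.black_factor
    return egfr


def estimate_baseline_scr(
    age: float,
    female: bool,
    black: bool,
    assumed_egfr: Optional[float] = None,
    params: MDRDParams = DEFAULT_MDRD,
) -> float:
    """Back-calculate the creatinine (mg/dL) at which MDRD gives `assumed_egfr`.

    Algebraic inversion of the closed form: the unique scr with
    mdrd_egfr(scr, ...) == assumed_egfr.
    """
    if assumed_egfr is None:
        assumed_egfr = params.assumed_normal_egfr
    if not assumed_egfr > 0:
        raise ValueError(f"assumed eGFR must be positive, got {assumed_egfr}")
    # eGFR at scr = 1 mg/dL carries all demographic factors
    egfr_at_unit_scr = mdrd_egfr(1.0, age, female, black, params)
    return (assumed_egfr / egfr_at_unit_scr) ** (1.0 / params.scr_exponent)


def resolve_baseline(
    encounter: Encounter,
    params: MDRDParams = DEFAULT_MDRD,
) -> BaselineResolution:
    """Charted baseline when present, MDRD estimate otherwise.

    A `baseline_creatinine` chart event takes the same precedence as the
    encounter-level charted value; the earliest charted baseline wins.
    """
    charted = encounter.charted_baseline_creatinine
    if charted is None:
        ev = encounter.events_of("baseline_creatinine")
        if len(ev):
            charted = float(ev["value"].iloc[0])
    if charted is not None:
        return BaselineResolution(value=float(charted), source="charted")
    demo = encounter.demographics
    if not demo.complete:
        raise ValueError(
            f"encounter {encounter.encounter_id}: cannot estimate baseline, demographics incomplete"
        )
    est = estimate_baseline_scr(
        demo.age, demo.sex == "female", bool(demo.race_black),
        assumed_egfr=params.assumed_normal_egfr, params=params,
    )
    return BaselineResolution(value=est, source="mdrd_estimated", assumed_egfr=params.assumed_normal_egfr)
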