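"""YAML configuration bundling for the pipeline.

A config file may carry any subset of the sections below; omitted keys use
the package defaults::

    creatinine_unit: mg/dL          # or umol/L
    staging:
      uo_stage1_rate: 0.5
      uo_window_mode: mean          # or all_hours
      ...
    mdrd:
      coefficient: 175
      assumed_normal_egfr: 75
      use_race_coefficient: true
    exclusions:
      min_los_hours: 24
      max_age_years: 90
      ...
    enoxaparin:
      dose_table:                   # list of [egfr_lower, egfr_upper, mg]
        - [0, 20, 0]
        - [20, 30, 20]
        - [30, .inf, 40]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from akiflow.enoxaparin import DEFAULT_DOSE_TABLE, DoseRule, validate_dose_table
from akiflow.io import ExclusionCriteria
from akiflow.renal import MDRDParams
from akiflow.staging import StagingRules


@dataclass
class AnalysisConfig:
    creatinine_unit: str = "mg/dL"
    staging: StagingRules = field(default_factory=StagingRules)
    mdrd: MDRDParams = field(default_factory=MDRDParams)
    exclusions: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    dose_table: tuple = DEFAULT_DOSE_TABLE


def _parse_dose_table(rows) -> tuple:
    rules = []
    for lower, upper, mg in rows:
        upper = math.inf if upper in (".inf", "inf", None) else float(upper)
        rules.append(DoseRule(float(lower), upper, float(mg)))
    return validate_dose_table(rules)


def load_config(path=None) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML; None gives all defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = AnalysisConfig()
    if "creatinine_unit" in raw:
        cfg.creatinine_unit = raw["creatinine_unit"]
    if raw.get("staging"):
        cfg.staging = StagingRules(**raw["staging"])
    if raw.get("mdrd"):
        cfg.mdrd = MDRDParams(**raw["mdrd"])
    if raw.get("exclusions"):
        cfg.exclusions = ExclusionCriteria(**raw["exclusions"])
    enox = raw.get("enoxaparin") or {}
    if enox.get("dose_table"):
        cfg.dose_table = _parse_dose_table(enox["dose_table"])
    return cfg
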