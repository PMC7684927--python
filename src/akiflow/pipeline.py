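"""End-to-end conveniences tying the modules together.

These are the steps the command-line interface and the analysis drivers
share: apply the exclusion cascade, resolve baselines, stage every
encounter, and collect per-encounter outcomes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from akiflow.config import AnalysisConfig
from akiflow.io import apply_exclusions
from akiflow.model import Encounter, ExclusionReport
from akiflow.outcomes import EncounterOutcomes, compute_outcomes
from akiflow.renal import resolve_baseline
from akiflow.staging import StageBundle, stage_encounter


def stage_cohort(
    encounters: Sequence[Encounter],
    config: Optional[AnalysisConfig] = None,
) -> "tuple[list[StageBundle], list[EncounterOutcomes]]":
    """Stage each encounter and derive its outcomes (no exclusions here)."""
    config = config or AnalysisConfig()
    bundles, outcomes = [], []
    for enc in encounters:
        baseline = resolve_baseline(enc, params=config.mdrd)
        bundle = stage_encounter(enc, baseline, rules=config.staging)
        bundles.append(bundle)
        outcomes.append(compute_outcomes(enc, bundle))
    return bundles, outcomes


def run_staging_pipeline(
    encounters: Sequence[Encounter],
    config: Optional[AnalysisConfig] = None,
) -> "tuple[list[Encounter], ExclusionReport, list[StageBundle], list[EncounterOutcomes]]":
    """Exclusion cascade, staging and outcomes in one pass."""
    config = config or AnalysisConfig()
    retained, report = apply_exclusions(encounters, config.exclusions)
    bundles, outcomes = stage_cohort(retained, config)
    return retained, report, bundles, outcomes


def stages_frame(bundles: Sequence[StageBundle]) -> pd.DataFrame:
    """Long-format stage table (encounter_id, timestamp, source, stage)."""
    if not bundles:
        return pd.DataFrame(columns=["encounter_id", "timestamp", "source", "stage"])
    return pd.concat([b.to_frame() for b in bundles], ignore_index=True)
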