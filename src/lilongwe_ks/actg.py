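"""ACTG tumor-extent (T) staging for the head-to-head comparison.

The AIDS Clinical Trials Group TIS system for adult HIV-related KS scores
tumor extent (T), immune status (I), and systemic illness (S). Only the T
axis is evaluated here: T1 for tumor-associated edema, extensive oral KS,
or visceral disease; T0 for disease confined to skin, lymph nodes, and/or
minimal (flat) oral lesions. "Extensive oral" is operationalized as any
nodular oral lesion; ulceration is not a schema field and is omitted.

The divergence from the Lilongwe stages is the point of the comparison:
every Lilongwe stage-3 (woody edema) patient is T1, while disseminated
skin/oral stage-4 patients without visceral disease remain T0 despite
their very poor survival.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .patient_model import LesionType, PatientRecord
from .staging import StageAssignment, classify_stage

__all__ = ["TStage", "TStageAssignment", "classify_t", "crosstab_stages"]


class TStage(str, enum.Enum):
    T0 = "T0"
    T1 = "T1"


@dataclass(frozen=True)
class TStageAssignment:
    value: TStage
    triggered_rules: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.value is TStage.T1) != bool(self.triggered_rules):
            raise ValueError("T1 iff at least one T1 criterion fired")


def classify_t(patient: PatientRecord) -> TStageAssignment:
    """Assign ACTG tumor-extent stage T0 or T1."""
    rules = []
    if patient.edema.woody:
        rules.append("tumor_associated_edema")
    if any(l.lesion_type is LesionType.NODULAR_ORAL for l in patient.lesions):
        rules.append("extensive_oral")
    if patient.visceral_pulmonary or patient.visceral_abdominal:
        rules.append("visceral")
    value = TStage.T1 if rules else TStage.T0
    return TStageAssignment(value, tuple(rules))


def crosstab_stages(
    cohort: Sequence[PatientRecord],
    stages: Sequence[StageAssignment] | None = None,
) -> pd.DataFrame:
    """Contingency table of Lilongwe stage (rows) by ACTG T stage (columns).

    Runs both classifiers when *stages* is not supplied. Cell counts sum to
    the cohort size; the frame serializes to CSV as-is.
    """
    if stages is None:
        stages = [classify_stage(p) for p in cohort]
    if len(stages) != len(cohort):
        raise ValueError("one stage assignment per patient is required")
    rows = [s.stage.value for s in stages]
    cols = [classify_t(p).value.value for p in cohort]
    table = pd.crosstab(
        pd.Series(rows, name="lilongwe_stage"), pd.Series(cols, name="t_stage")
    )
    return table.reindex(columns=["T0", "T1"], fill_value=0)
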