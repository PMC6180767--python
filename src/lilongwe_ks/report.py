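"""Table-1-style per-stage cohort report.

One row per stage (3A and 3B reported separately with a pooled stage-3
subtotal): sample size, percent of cohort, mean age, mean CD4, lymph-node
and oral-involvement percentages, cART-at-diagnosis percentage,
induction-failure percentage, deaths, and 24-month EFS/OS.

Induction failure has no per-patient schema field; the report counts an
EFS event within the first :data:`INDUCTION_WINDOW_MONTHS` months (four
three-week BV cycles plus response assessment) as an induction failure.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .patient_model import PatientRecord, Region
from .staging import StageAssignment
from .survival import DEFAULT_HORIZON_MONTHS, km_fit, survival_at

__all__ = ["build_report", "INDUCTION_WINDOW_MONTHS"]

#: Months after diagnosis by which induction-phase response is assessed.
INDUCTION_WINDOW_MONTHS: float = 8.0

_ORAL_REGIONS = {Region.ORAL_CAVITY}


def _row(
    label: str,
    patients: list[PatientRecord],
    total_n: int,
    horizon: float,
) -> dict:
    n = len(patients)
    if n == 0:
        return {"stage": label, "n": 0, "pct_of_cohort": 0.0}
    ages = [p.age_years for p in patients]
    cd4 = [p.cd4_count_cells_per_uL for p in patients if p.cd4_count_cells_per_uL is not None]
    efs_t = [p.outcome.efs_time_months for p in patients]
    efs_e = [p.outcome.efs_event for p in patients]
    os_t = [p.outcome.os_time_months for p in patients]
    os_e = [p.outcome.os_event for p in patients]
    return {
        "stage": label,
        "n": n,
        "pct_of_cohort": 100 * n / total_n,
        "mean_age_years": float(np.mean(ages)),
        "mean_cd4": float(np.mean(cd4)) if cd4 else float("nan"),
        "lymph_node_pct": 100 * np.mean([p.lymph_node_involvement for p in patients]),
        "oral_involvement_pct": 100
        * np.mean(
            [any(l.region in _ORAL_REGIONS for l in p.lesions) for p in patients]
        ),
        "cart_pct": 100 * np.mean([p.on_cart_at_diagnosis for p in patients]),
        "induction_failure_pct": 100
        * np.mean(
            [
                p.outcome.efs_event
                and p.outcome.efs_time_months <= INDUCTION_WINDOW_MONTHS
                for p in patients
            ]
        ),
        "deaths": int(sum(os_e)),
        f"efs_{horizon:g}mo_pct": 100 * survival_at(km_fit(efs_t, efs_e), horizon),
        f"os_{horizon:g}mo_pct": 100 * survival_at(km_fit(os_t, os_e), horizon),
    }


def build_report(
    cohort: Sequence[PatientRecord],
    stages: Sequence[StageAssignment],
    horizon: float = DEFAULT_HORIZON_MONTHS,
) -> pd.DataFrame:
    """Per-stage clinical-characteristics and outcome table."""
    if len(cohort) != len(stages):
        raise ValueError("one stage assignment per patient is required")
    total = len(cohort)
    by_label: dict[str, list[PatientRecord]] = {}
    for patient, assignment in zip(cohort, stages):
        by_label.setdefault(assignment.stage.value, []).append(patient)
    rows = []
    for label in ("1", "2", "3A", "3B"):
        if label in by_label:
            rows.append(_row(label, by_label[label], total, horizon))
    pooled3 = by_label.get("3A", []) + by_label.get("3B", [])
    if pooled3:
        rows.append(_row("3 (all)", pooled3, total, horizon))
    if "4" in by_label:
        rows.append(_row("4", by_label["4"], total, horizon))
    frame = pd.DataFrame(rows).set_index("stage")
    return frame


def format_report(frame: pd.DataFrame) -> str:
    """Aligned plain-text rendering of :func:`build_report` output."""
    return frame.round(1).to_string()
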