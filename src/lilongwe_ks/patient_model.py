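"""Domain types for pediatric Kaposi sarcoma records and cohort I/O.

One :class:`PatientRecord` captures a child's clinical picture at KS
diagnosis — lesion inventory, lymph node / visceral / edema findings,
HIV treatment context — plus the event-free and overall survival outcome.
Records validate on construction; cohorts round-trip losslessly through
JSON and CSV interchange formats (see :func:`read_cohort` /
:func:`write_cohort` and ``docs/schema.md``).
"""

from __future__ import annotations

import csv
import enum
import json
import math
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "LesionType",
    "Region",
    "BSA_REGIONS",
    "CytopeniaGrade",
    "Regimen",
    "CauseOfDeath",
    "Lesion",
    "EdemaMap",
    "OutcomeRecord",
    "PatientRecord",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]


class LesionType(str, enum.Enum):
    """Morphologic lesion categories used by the staging rules."""

    HYPERPIGMENTED_SKIN = "hyperpigmented_skin"
    FLAT_ORAL = "flat_oral"
    NODULAR_ORAL = "nodular_oral"
    SUBCUTANEOUS_NODULE = "subcutaneous_nodule"  # flesh-colored
    CONJUNCTIVAL = "conjunctival"
    EXOPHYTIC_MASS = "exophytic_mass"


class Region(str, enum.Enum):
    """Anatomic regions: the 7 cutaneous Rule-of-9s regions plus perineum,
    oral cavity, conjunctiva, and a catch-all."""

    HEAD_NECK = "head_neck"
    ANTERIOR_TRUNK = "anterior_trunk"
    POSTERIOR_TRUNK = "posterior_trunk"
    LEFT_ARM = "left_arm"
    RIGHT_ARM = "right_arm"
    LEFT_LEG = "left_leg"
    RIGHT_LEG = "right_leg"
    PERINEUM = "perineum"
    ORAL_CAVITY = "oral_cavity"
    CONJUNCTIVA = "conjunctiva"
    OTHER = "other"


#: Regions carrying body-surface-area weight (edema can involve these).
BSA_REGIONS: tuple[Region, ...] = (
    Region.HEAD_NECK,
    Region.ANTERIOR_TRUNK,
    Region.POSTERIOR_TRUNK,
    Region.LEFT_ARM,
    Region.RIGHT_ARM,
    Region.LEFT_LEG,
    Region.RIGHT_LEG,
    Region.PERINEUM,
)


class CytopeniaGrade(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


class Regimen(str, enum.Enum):
    CART_ONLY = "cart_only"
    BV = "bv"
    ABV = "abv"
    PACLITAXEL = "paclitaxel"


class CauseOfDeath(str, enum.Enum):
    KS = "ks"
    HIV_LATE_IN_CR = "hiv_late_in_cr"  # late death in complete remission
    HIV_EARLY_OI = "hiv_early_oi"  # early death, concurrent opportunistic infection
    OTHER = "other"
    NOT_APPLICABLE = "not_applicable"


class Lesion(BaseModel):
    """A single lesion, or one member of a confluent cluster.

    Coalescing/confluent hyperpigmented skin lesions within one anatomic
    region may share a ``cluster_id``; the stager counts each cluster as a
    single lesion. ``longest_diameter_mm`` supports response assessment.
    """

    model_config = ConfigDict(frozen=True)

    lesion_type: LesionType
    region: Region
    cluster_id: Optional[str] = None
    longest_diameter_mm: Optional[float] = Field(default=None, gt=0)


class EdemaMap(BaseModel):
    """Per-region fraction of surface involved by woody (non-pitting) KS edema.

    ``facial_edema`` is tracked separately: it is a stage-2 trigger, distinct
    from the woody edema that defines stage 3.
    """

    model_config = ConfigDict(frozen=True)

    fractions: dict[Region, float] = Field(default_factory=dict)
    woody: bool = False
    facial_edema: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EdemaMap":
        for region, frac in self.fractions.items():
            if region not in BSA_REGIONS:
                raise ValueError(
                    f"edema fraction given for non-BSA region {region.value!r}"
                )
            if not (0.0 <= frac <= 1.0):
                raise ValueError(
                    f"edema fraction for {region.value} must lie in [0, 1], got {frac}"
                )
        if not self.woody and any(f > 0 for f in self.fractions.values()):
            raise ValueError("nonzero edema fractions require woody=True")
        return self


class OutcomeRecord(BaseModel):
    """EFS/OS outcome for one patient.

    EFS events are induction failure, disease progression or relapse, or
    death from any cause; OS events are deaths from any cause. A death is
    itself an EFS event, so ``os_event`` with ``efs_time == os_time``
    requires ``efs_event``; an earlier ``efs_time`` with ``efs_event=False``
    represents EFS censored at the last disease assessment before death.
    """

    model_config = ConfigDict(frozen=True)

    efs_time_months: float = Field(gt=0)
    efs_event: bool
    os_time_months: float = Field(gt=0)
    os_event: bool
    cause_of_death: CauseOfDeath = CauseOfDeath.NOT_APPLICABLE

    @model_validator(mode="after")
    def _check(self) -> "OutcomeRecord":
        if self.efs_time_months > self.os_time_months:
            raise ValueError(
                f"efs_time_months ({self.efs_time_months}) exceeds "
                f"os_time_months ({self.os_time_months})"
            )
        if not self.os_event and self.cause_of_death is not CauseOfDeath.NOT_APPLICABLE:
            raise ValueError("cause_of_death requires os_event=True")
        if self.os_event and self.cause_of_death is CauseOfDeath.NOT_APPLICABLE:
            raise ValueError("os_event=True requires a cause_of_death")
        if (
            self.os_event
            and not self.efs_event
            and math.isclose(self.efs_time_months, self.os_time_months)
        ):
            raise ValueError(
                "death at efs_time is an EFS event; set efs_event=True or "
                "censor EFS strictly before os_time"
            )
        return self


class PatientRecord(BaseModel):
    """One child's full clinical picture at KS diagnosis plus outcome."""

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age_years: float = Field(ge=0)
    on_cart_at_diagnosis: bool
    cd4_count_cells_per_uL: Optional[float] = Field(default=None, ge=0)
    cytopenia_grade: CytopeniaGrade = CytopeniaGrade.NONE
    lesions: tuple[Lesion, ...] = ()
    lymph_node_involvement: bool = False
    visceral_pulmonary: bool = False
    visceral_abdominal: bool = False
    edema: EdemaMap = Field(default_factory=EdemaMap)
    widespread_distribution: Optional[bool] = None
    regimen: Regimen = Regimen.BV
    outcome: OutcomeRecord

    @model_validator(mode="after")
    def _check(self) -> "PatientRecord":
        if self.age_years >= 18:
            raise ValueError(
                f"age_years must be < 18 (pediatric cohort), got {self.age_years}"
            )
        # lesions sharing a cluster_id must share a region
        regions_by_cluster: dict[str, Region] = {}
        for lesion in self.lesions:
            if lesion.cluster_id is None:
                continue
            seen = regions_by_cluster.setdefault(lesion.cluster_id, lesion.region)
            if seen is not lesion.region:
                raise ValueError(
                    f"cluster {lesion.cluster_id!r} spans regions "
                    f"{seen.value!r} and {lesion.region.value!r}; confluent "
                    "clusters must be localized to one anatomic region"
                )
        return self


class CohortValidationError(ValueError):
    """Structured rejection naming the offending patient and field."""

    def __init__(self, message: str, patient_id: str | None = None):
        self.patient_id = patient_id
        super().__init__(
            message if patient_id is None else f"patient {patient_id!r}: {message}"
        )


# ---------------------------------------------------------------------------
# serialization


def _record_to_obj(record: PatientRecord) -> dict:
    obj = record.model_dump(mode="json")
    # edema fractions keyed by region string already via mode="json"
    return obj


def _obj_to_record(obj: dict) -> PatientRecord:
    pid = obj.get("patient_id") if isinstance(obj, dict) else None
    try:
        return PatientRecord.model_validate(obj)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<record>"
        raise CohortValidationError(
            f"field {loc!r}: {first['msg']}", patient_id=pid
        ) from err


_SCALAR_COLUMNS = [
    "patient_id",
    "age_years",
    "on_cart_at_diagnosis",
    "cd4_count_cells_per_uL",
    "cytopenia_grade",
    "lymph_node_involvement",
    "visceral_pulmonary",
    "visceral_abdominal",
    "woody_edema",
    "facial_edema",
    "widespread_distribution",
    "regimen",
    "efs_time_months",
    "efs_event",
    "os_time_months",
    "os_event",
    "cause_of_death",
] + [f"edema_frac_{r.value}" for r in BSA_REGIONS]

_LESION_COLUMNS = [
    "patient_id",
    "lesion_type",
    "region",
    "cluster_id",
    "longest_diameter_mm",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(text: str, column: str, pid: str) -> Optional[bool]:
    if text == "":
        return None
    if text == "true":
        return True
    if text == "false":
        return False
    raise CohortValidationError(
        f"field {column!r}: expected 'true'/'false', got {text!r}", patient_id=pid
    )


def lesion_table_path(path: Path | str) -> Path:
    """Companion long-format lesion table for a scalar CSV at *path*."""
    path = Path(path)
    return path.with_name(path.stem + "_lesions" + path.suffix)


def _write_csv(cohort: list[PatientRecord], path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SCALAR_COLUMNS)
        for rec in cohort:
            row = {
                "patient_id": rec.patient_id,
                "age_years": rec.age_years,
                "on_cart_at_diagnosis": rec.on_cart_at_diagnosis,
                "cd4_count_cells_per_uL": rec.cd4_count_cells_per_uL,
                "cytopenia_grade": rec.cytopenia_grade.value,
                "lymph_node_involvement": rec.lymph_node_involvement,
                "visceral_pulmonary": rec.visceral_pulmonary,
                "visceral_abdominal": rec.visceral_abdominal,
                "woody_edema": rec.edema.woody,
                "facial_edema": rec.edema.facial_edema,
                "widespread_distribution": rec.widespread_distribution,
                "regimen": rec.regimen.value,
                "efs_time_months": rec.outcome.efs_time_months,
                "efs_event": rec.outcome.efs_event,
                "os_time_months": rec.outcome.os_time_months,
                "os_event": rec.outcome.os_event,
                "cause_of_death": rec.outcome.cause_of_death.value,
            }
            for region in BSA_REGIONS:
                row[f"edema_frac_{region.value}"] = rec.edema.fractions.get(region, 0.0)
            writer.writerow([_fmt(row[c]) for c in _SCALAR_COLUMNS])
    with open(lesion_table_path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LESION_COLUMNS)
        for rec in cohort:
            for lesion in rec.lesions:
                writer.writerow(
                    [
                        rec.patient_id,
                        lesion.lesion_type.value,
                        lesion.region.value,
                        _fmt(lesion.cluster_id),
                        _fmt(lesion.longest_diameter_mm),
                    ]
                )


def _read_csv(path: Path) -> list[PatientRecord]:
    lesions_by_pid: dict[str, list[dict]] = {}
    lesion_path = lesion_table_path(path)
    if lesion_path.exists():
        with open(lesion_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                pid = row["patient_id"]
                lesions_by_pid.setdefault(pid, []).append(
                    {
                        "lesion_type": row["lesion_type"],
                        "region": row["region"],
                        "cluster_id": row["cluster_id"] or None,
                        "longest_diameter_mm": float(row["longest_diameter_mm"])
                        if row["longest_diameter_mm"]
                        else None,
                    }
                )
    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            fractions = {
                r.value: float(row[f"edema_frac_{r.value}"] or 0.0)
                for r in BSA_REGIONS
                if float(row.get(f"edema_frac_{r.value}") or 0.0) != 0.0
            }
            obj = {
                "patient_id": pid,
                "age_years": float(row["age_years"]),
                "on_cart_at_diagnosis": _parse_bool(
                    row["on_cart_at_diagnosis"], "on_cart_at_diagnosis", pid
                ),
                "cd4_count_cells_per_uL": float(row["cd4_count_cells_per_uL"])
                if row["cd4_count_cells_per_uL"]
                else None,
                "cytopenia_grade": row["cytopenia_grade"],
                "lesions": lesions_by_pid.get(pid, []),
                "lymph_node_involvement": _parse_bool(
                    row["lymph_node_involvement"], "lymph_node_involvement", pid
                ),
                "visceral_pulmonary": _parse_bool(
                    row["visceral_pulmonary"], "visceral_pulmonary", pid
                ),
                "visceral_abdominal": _parse_bool(
                    row["visceral_abdominal"], "visceral_abdominal", pid
                ),
                "edema": {
                    "fractions": fractions,
                    "woody": _parse_bool(row["woody_edema"], "woody_edema", pid),
                    "facial_edema": _parse_bool(
                        row["facial_edema"], "facial_edema", pid
                    ),
                },
                "widespread_distribution": _parse_bool(
                    row["widespread_distribution"], "widespread_distribution", pid
                ),
                "regimen": row["regimen"],
                "outcome": {
                    "efs_time_months": float(row["efs_time_months"]),
                    "efs_event": _parse_bool(row["efs_event"], "efs_event", pid),
                    "os_time_months": float(row["os_time_months"]),
                    "os_event": _parse_bool(row["os_event"], "os_event", pid),
                    "cause_of_death": row["cause_of_death"],
                },
            }
            records.append(_obj_to_record(obj))
    return records


def read_cohort(path: Path | str, format: str | None = None) -> list[PatientRecord]:
    """Read and validate a cohort file.

    Parameters
    ----------
    path:
        JSON file (array of patient objects) or scalar CSV with its
        companion ``*_lesions`` long-format table alongside.
    format:
        ``"json"`` or ``"csv"``; inferred from the suffix when omitted.

    Every record is validated against all schema invariants; the first
    violation raises :class:`CohortValidationError` naming the patient and
    field. Row order is preserved.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise CohortValidationError("JSON cohort must be an array of patients")
        return [_obj_to_record(obj) for obj in data]
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown cohort format {fmt!r} (expected 'csv' or 'json')")


def write_cohort(
    cohort: list[PatientRecord], path: Path | str, format: str | None = None
) -> None:
    """Write a validated cohort; ``read_cohort`` reproduces it field-for-field."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([_record_to_obj(r) for r in cohort], fh, indent=1)
            fh.write("\n")
    elif fmt == "csv":
        _write_csv(cohort, path)
    else:
        raise ValueError(f"unknown cohort format {fmt!r} (expected 'csv' or 'json')")
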