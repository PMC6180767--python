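"""The Lilongwe pediatric KS staging classification.

Four stages, assigned with precedence 4 → 3 → 1 → 2:

* **Stage 1 — Mild KS.** Disease limited to hyperpigmented skin lesions,
  flat oral lesions, and/or flesh-colored subcutaneous nodules, with fewer
  than 10 lesions total (cluster-collapsed).
* **Stage 2 — Lymphadenopathic KS.** Lymph node involvement, nodular oral
  lesions, facial edema, conjunctival lesions, exophytic masses, or 10–19
  hyperpigmented skin/oral lesions; the residual class for any patient not
  meeting stages 1, 3 or 4.
* **Stage 3 — Woody Edema KS.** Woody (non-pitting) edema, with or without
  stage-1/2 features; substage 3A below 10% of estimated BSA involved,
  3B at or above (Wallace Rule of 9s).
* **Stage 4 — Visceral and/or Disseminated Skin/Oral KS.** Pulmonary or
  abdominal visceral involvement, and/or ≥ 20 hyperpigmented skin/oral
  lesions in a widespread distribution (excluding flesh-colored
  subcutaneous nodules), with or without features of the other stages.

Coalescing/confluent hyperpigmented skin lesions localized to one anatomic
region count as one lesion per cluster. "Widespread distribution" is not
quantitatively defined by the classification; this implementation uses
cluster-collapsed hyperpigmented skin/oral lesions occupying at least
:data:`WIDESPREAD_MIN_REGIONS` distinct anatomic regions, overridable per
record by ``widespread_distribution`` (clinician adjudication wins).

Cytopenias are deliberately absent from the rules: moderate-severe
cytopenias were not associated with inferior survival in the source cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .bsa import bsa_substage, estimate_bsa_percent
from .patient_model import Lesion, LesionType, PatientRecord, Region

__all__ = [
    "Stage",
    "LesionTally",
    "StageAssignment",
    "ResponseAssessment",
    "WIDESPREAD_MIN_REGIONS",
    "count_lesions",
    "is_widespread",
    "classify_stage",
    "classify_cohort",
    "assess_induction",
]

#: Minimum number of distinct anatomic regions occupied by (cluster-collapsed)
#: hyperpigmented skin/oral lesions for "widespread distribution".
WIDESPREAD_MIN_REGIONS: int = 3

#: Cluster-collapsed hyperpigmented skin/oral lesion count defining
#: disseminated skin/oral disease (a stage-4 criterion when widespread).
DISSEMINATED_LESION_THRESHOLD: int = 20

#: Stage-1 cap: fewer than this many (cluster-collapsed) lesions total.
STAGE1_MAX_LESIONS: int = 10

#: Lesion types compatible with stage 1 (mild) disease.
STAGE1_LESION_TYPES = frozenset(
    {LesionType.HYPERPIGMENTED_SKIN, LesionType.FLAT_ORAL, LesionType.SUBCUTANEOUS_NODULE}
)

#: Lesion types counted in the hyperpigmented skin/oral tally. Flat and
#: nodular oral lesions count; flesh-colored subcutaneous nodules are the
#: classification's sole stated exclusion.
HYPERPIGMENTED_TALLY_TYPES = frozenset(
    {LesionType.HYPERPIGMENTED_SKIN, LesionType.FLAT_ORAL, LesionType.NODULAR_ORAL}
)


class Stage(str, enum.Enum):
    S1 = "1"
    S2 = "2"
    S3A = "3A"
    S3B = "3B"
    S4 = "4"

    @property
    def pooled(self) -> str:
        """Major stage with 3A/3B pooled ('1', '2', '3', '4')."""
        return self.value.rstrip("AB")


@dataclass(frozen=True)
class LesionTally:
    """Cluster-collapsed lesion counts by category."""

    hyperpigmented_skin_oral: int  # skin + flat/nodular oral, clusters collapsed
    flat_oral: int
    nodular_oral: int
    subcutaneous_nodule: int
    conjunctival: int
    exophytic_mass: int
    total: int  # all categories, clusters collapsed

    @property
    def stage1_total(self) -> int:
        """Cluster-collapsed total over the three stage-1-permitted types."""
        return (
            self.hyperpigmented_skin_oral
            - self.nodular_oral
            + self.subcutaneous_nodule
        )


@dataclass(frozen=True)
class StageAssignment:
    """A stage plus the rules that fired and the tallies used."""

    stage: Stage
    triggered_rules: tuple[str, ...]
    counted_lesions: LesionTally
    bsa_percent: float = 0.0

    def __post_init__(self) -> None:
        if not self.triggered_rules:
            raise ValueError("triggered_rules must be non-empty")


def _collapse(lesions: Iterable[Lesion]) -> list[Lesion]:
    """Collapse confluent clusters of hyperpigmented skin lesions to one
    representative each; all other lesions pass through individually."""
    out: list[Lesion] = []
    seen_clusters: dict[tuple[Region, str], Region] = {}
    for lesion in lesions:
        if (
            lesion.lesion_type is LesionType.HYPERPIGMENTED_SKIN
            and lesion.cluster_id is not None
        ):
            key = (lesion.region, lesion.cluster_id)
            if key in seen_clusters:
                continue
            # a cluster_id reused across regions violates localization
            for (other_region, cid) in seen_clusters:
                if cid == lesion.cluster_id and other_region is not lesion.region:
                    raise ValueError(
                        f"cluster {lesion.cluster_id!r} spans regions "
                        f"{other_region.value!r} and {lesion.region.value!r}"
                    )
            seen_clusters[key] = lesion.region
            out.append(lesion)
        else:
            out.append(lesion)
    return out


def count_lesions(lesions: Sequence[Lesion]) -> LesionTally:
    """Tally lesions by category after collapsing confluent clusters.

    Each (region, cluster_id) group of hyperpigmented skin lesions
    contributes one lesion; unclustered lesions count individually. The
    hyperpigmented skin/oral tally spans hyperpigmented skin plus flat and
    nodular oral lesions and excludes flesh-colored subcutaneous nodules.
    """
    collapsed = _collapse(lesions)
    by_type: dict[LesionType, int] = {t: 0 for t in LesionType}
    for lesion in collapsed:
        by_type[lesion.lesion_type] += 1
    return LesionTally(
        hyperpigmented_skin_oral=sum(
            by_type[t] for t in HYPERPIGMENTED_TALLY_TYPES
        ),
        flat_oral=by_type[LesionType.FLAT_ORAL],
        nodular_oral=by_type[LesionType.NODULAR_ORAL],
        subcutaneous_nodule=by_type[LesionType.SUBCUTANEOUS_NODULE],
        conjunctival=by_type[LesionType.CONJUNCTIVAL],
        exophytic_mass=by_type[LesionType.EXOPHYTIC_MASS],
        total=len(collapsed),
    )


def is_widespread(
    lesions: Sequence[Lesion],
    override: bool | None = None,
    min_regions: int = WIDESPREAD_MIN_REGIONS,
) -> bool:
    """Whether hyperpigmented skin/oral lesions show a widespread distribution.

    Operationalized as cluster-collapsed hyperpigmented skin/oral lesions
    occupying at least *min_regions* distinct anatomic regions. A non-None
    *override* (clinician adjudication) takes precedence.
    """
    if override is not None:
        return override
    regions = {
        lesion.region
        for lesion in _collapse(lesions)
        if lesion.lesion_type in HYPERPIGMENTED_TALLY_TYPES
    }
    return len(regions) >= min_regions


def classify_stage(
    patient: PatientRecord, widespread_min_regions: int = WIDESPREAD_MIN_REGIONS
) -> StageAssignment:
    """Assign the Lilongwe stage to one patient record.

    Precedence is stage 4, then 3, then 1, with stage 2 as the residual
    class. ``triggered_rules`` lists every satisfied criterion of the
    assigned stage, in rule order.
    """
    tally = count_lesions(patient.lesions)
    widespread = is_widespread(
        patient.lesions,
        override=patient.widespread_distribution,
        min_regions=widespread_min_regions,
    )
    bsa = estimate_bsa_percent(patient.edema)

    # stage 4: visceral and/or disseminated skin/oral
    s4_rules = []
    if patient.visceral_pulmonary:
        s4_rules.append("visceral_pulmonary")
    if patient.visceral_abdominal:
        s4_rules.append("visceral_abdominal")
    if tally.hyperpigmented_skin_oral >= DISSEMINATED_LESION_THRESHOLD and widespread:
        s4_rules.append("hyperpigmented_ge20_widespread")
    if s4_rules:
        return StageAssignment(Stage.S4, tuple(s4_rules), tally, bsa)

    # stage 3: woody edema, substaged by BSA
    if patient.edema.woody:
        sub = bsa_substage(bsa)
        stage = Stage.S3A if sub == "A" else Stage.S3B
        return StageAssignment(
            stage, ("woody_edema", f"bsa_substage_{sub}"), tally, bsa
        )

    # stage 1: mild — restricted lesion types, < 10 total, no stage-2 findings
    types_present = {lesion.lesion_type for lesion in patient.lesions}
    if (
        types_present <= STAGE1_LESION_TYPES
        and tally.total < STAGE1_MAX_LESIONS
        and not patient.lymph_node_involvement
        and not patient.edema.facial_edema
    ):
        return StageAssignment(Stage.S1, ("mild_lt10_lesions",), tally, bsa)

    # stage 2: residual class; record each satisfied criterion
    s2_rules = []
    if patient.lymph_node_involvement:
        s2_rules.append("lymph_node_involvement")
    if tally.nodular_oral > 0:
        s2_rules.append("nodular_oral")
    if patient.edema.facial_edema:
        s2_rules.append("facial_edema")
    if tally.conjunctival > 0:
        s2_rules.append("conjunctival")
    if tally.exophytic_mass > 0:
        s2_rules.append("exophytic_mass")
    if 10 <= tally.hyperpigmented_skin_oral <= 19:
        s2_rules.append("hyperpigmented_10_19")
    if not s2_rules:
        s2_rules.append("residual_stage2")
    return StageAssignment(Stage.S2, tuple(s2_rules), tally, bsa)


def classify_cohort(
    cohort: Sequence[PatientRecord], **kwargs
) -> list[StageAssignment]:
    """Vector convenience: :func:`classify_stage` over a cohort."""
    return [classify_stage(p, **kwargs) for p in cohort]


@dataclass(frozen=True)
class ResponseAssessment:
    """Per-lesion induction response and the induction-failure verdict.

    Induction failure: inability to achieve more than 90% reduction in size
    of *all* lesions after induction-phase treatment (four BV cycles).
    Success therefore requires every lesion reduced by strictly more than
    90%; a lesion at exactly 90% reduction fails.
    """

    baselines_mm: tuple[float, ...]
    post_induction_mm: tuple[float, ...]
    reductions: tuple[float, ...] = field(init=False)
    induction_failure: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.baselines_mm) != len(self.post_induction_mm):
            raise ValueError("each lesion needs a baseline and a post-induction diameter")
        if not self.baselines_mm:
            raise ValueError("at least one lesion is required")
        if any(d <= 0 for d in self.baselines_mm) or any(
            d <= 0 for d in self.post_induction_mm
        ):
            raise ValueError("diameters must be positive")
        reductions = tuple(
            (base - post) / base
            for base, post in zip(self.baselines_mm, self.post_induction_mm)
        )
        object.__setattr__(self, "reductions", reductions)
        object.__setattr__(
            self, "induction_failure", any(r <= 0.90 for r in reductions)
        )


def assess_induction(
    pairs: Sequence[tuple[float, float]]
) -> ResponseAssessment:
    """Assess induction response from (baseline, post-induction) diameter
    pairs in millimetres."""
    baselines = tuple(p[0] for p in pairs)
    post = tuple(p[1] for p in pairs)
    return ResponseAssessment(baselines, post)
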