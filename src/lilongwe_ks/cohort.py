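"""Synthetic pediatric KS cohorts with the Lilongwe cohort's structure.

The generator emulates the 68-patient retrospective cohort behind the
staging classification: per-stage sample sizes 0/37/14/17, the reported
covariate structure (stage 2 youngest with lymphadenopathy enriched and
19/37 on cART at diagnosis, 13/18 of the remainder with moderate-severe
cytopenias; stage 3 oldest, mean age 12.6 years; stage 4 with the lowest
CD4 and oral involvement enriched), and per-stage outcome tables whose
Kaplan–Meier estimates reproduce the printed 2-year EFS/OS values.

Outcome times come from frozen per-patient tables rather than parametric
draws: with 14–37 patients per stage only explicit tables can reproduce
the printed product-limit values exactly. The tables are ONE admissible
configuration consistent with every printed number (the real per-patient
censoring pattern is unknowable); :func:`validate_outcome_tables` checks
the full constraint set with the package's own Kaplan–Meier fitter. An
exponential outcome mode is available for power exploration and is
clearly NOT calibrated to the printed values.

Every generated record is re-classified at generation time; a mismatch
between the latent stage and :func:`~lilongwe_ks.staging.classify_stage`
is a hard error, which makes round-trip stage recovery exact by
construction on every cohort the generator emits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .patient_model import (
    CauseOfDeath,
    CytopeniaGrade,
    EdemaMap,
    Lesion,
    LesionType,
    OutcomeRecord,
    PatientRecord,
    Region,
    Regimen,
)
from .staging import Stage, classify_stage
from .survival import km_fit, survival_at

__all__ = [
    "CohortConfig",
    "DEFAULT_SEED",
    "generate_cohort",
    "reference_cohort",
    "build_outcome_tables",
    "validate_outcome_tables",
]

#: Documented seed of the packaged reference cohort.
DEFAULT_SEED: int = 68

_CUTANEOUS = [
    Region.HEAD_NECK,
    Region.ANTERIOR_TRUNK,
    Region.POSTERIOR_TRUNK,
    Region.LEFT_ARM,
    Region.RIGHT_ARM,
    Region.LEFT_LEG,
    Region.RIGHT_LEG,
]


@dataclass(frozen=True)
class _OutcomeRow:
    efs_time: float
    efs_event: bool
    os_time: float
    os_event: bool
    cause: CauseOfDeath = CauseOfDeath.NOT_APPLICABLE
    regimen: Regimen = Regimen.BV


def _alive(fu: float, regimen: Regimen = Regimen.BV) -> _OutcomeRow:
    return _OutcomeRow(fu, False, fu, False, CauseOfDeath.NOT_APPLICABLE, regimen)


# ---------------------------------------------------------------------------
# Frozen outcome tables (months). Derived to satisfy, simultaneously:
#   stage 2: KM_EFS(24) = 27/37 (73%); KM_OS(24) = 27/36 = 75% with exactly
#            one patient censored before the first death; 10 deaths
#            (4 KS, 4 late HIV deaths in CR, 2 early deaths with OI).
#   stage 3: KM_EFS(24) = 4/14 = 28.6%; KM_OS(24) = 11/14 = 78.6%;
#            4 deaths, all non-KS, three before month 24 and one after.
#   stage 4: KM_EFS(24) = 0; KM_OS(24) = 2/17 = 11.8%; 15 deaths, all KS;
#            the 12 pre-doxorubicin deaths have median 3 months (longest 7);
#            the three ABV deaths at 4, 9 and 12 months; two ABV-treated
#            survivors alive at 17 and 27 months.
#   cohort:  survivor follow-up within [15, 50] months, median 28.

_STAGE2_ROWS: tuple[_OutcomeRow, ...] = (
    # progression at 3 months, then lost to follow-up alive at 15 months —
    # the one subject censored before the first death
    _OutcomeRow(3.0, True, 15.0, False),
    # early deaths with concurrent opportunistic infection
    _OutcomeRow(16.0, True, 16.0, True, CauseOfDeath.HIV_EARLY_OI),
    _OutcomeRow(16.5, True, 16.5, True, CauseOfDeath.HIV_EARLY_OI),
    # KS deaths, progression preceding death
    _OutcomeRow(14.0, True, 17.0, True, CauseOfDeath.KS),
    _OutcomeRow(15.0, True, 18.0, True, CauseOfDeath.KS),
    _OutcomeRow(16.0, True, 19.0, True, CauseOfDeath.KS),
    _OutcomeRow(17.0, True, 20.0, True, CauseOfDeath.KS),
    # late deaths in complete remission (uncontrolled HIV)
    _OutcomeRow(20.5, True, 20.5, True, CauseOfDeath.HIV_LATE_IN_CR),
    _OutcomeRow(21.0, True, 21.0, True, CauseOfDeath.HIV_LATE_IN_CR),
    _OutcomeRow(22.0, True, 22.0, True, CauseOfDeath.HIV_LATE_IN_CR),
    _OutcomeRow(30.0, True, 30.0, True, CauseOfDeath.HIV_LATE_IN_CR),
) + tuple(
    _alive(fu)
    for fu in (
        24.0, 24.5, 25.0, 25.5, 26.0, 26.5, 27.0, 27.5, 28.0, 28.0, 28.0,
        28.0, 29.0, 30.0, 31.0, 32.0, 33.0, 34.0, 35.0, 36.0, 38.0, 40.0,
        42.0, 44.0, 46.0, 50.0,
    )
)

# First four rows: complete remission (the four 3A patients); then six
# induction failures alive with stable disease; then four induction
# failures who later died of non-KS causes.
_STAGE3_ROWS: tuple[_OutcomeRow, ...] = (
    _alive(25.0),
    _alive(28.0),
    _alive(35.0),
    _alive(41.0),
    _OutcomeRow(4.0, True, 24.0, False),
    _OutcomeRow(5.0, True, 26.0, False),
    _OutcomeRow(6.0, True, 27.0, False),
    _OutcomeRow(6.5, True, 30.0, False),
    _OutcomeRow(7.0, True, 32.0, False),
    _OutcomeRow(8.0, True, 38.0, False),
    _OutcomeRow(4.5, True, 10.0, True, CauseOfDeath.OTHER),
    _OutcomeRow(5.0, True, 15.0, True, CauseOfDeath.OTHER),
    _OutcomeRow(5.5, True, 20.0, True, CauseOfDeath.OTHER),
    _OutcomeRow(6.0, True, 30.0, True, CauseOfDeath.OTHER),
)

_STAGE4_ROWS: tuple[_OutcomeRow, ...] = tuple(
    _OutcomeRow(t, True, t, True, CauseOfDeath.KS, Regimen.BV)
    for t in (1.0, 1.5, 2.0, 2.5, 2.75, 3.0, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0)
) + (
    _OutcomeRow(3.0, True, 4.0, True, CauseOfDeath.KS, Regimen.ABV),
    _OutcomeRow(3.0, True, 9.0, True, CauseOfDeath.KS, Regimen.ABV),
    _OutcomeRow(3.0, True, 12.0, True, CauseOfDeath.KS, Regimen.ABV),
    _OutcomeRow(3.0, True, 17.0, False, regimen=Regimen.ABV),
    _OutcomeRow(3.0, True, 27.0, False, regimen=Regimen.ABV),
)

# Stage-1 template (no such patients in the reference cohort): mild disease
# managed on cART alone, alive through follow-up.
_STAGE1_FU: tuple[float, ...] = (26.0, 30.0, 34.0, 38.0, 42.0)

_FROZEN_ROWS: dict[int, tuple[_OutcomeRow, ...]] = {
    2: _STAGE2_ROWS,
    3: _STAGE3_ROWS,
    4: _STAGE4_ROWS,
}


class _StageCovariates(BaseModel):
    model_config = ConfigDict(frozen=True)

    age_mean_years: float
    age_sd_years: float
    cd4_mean: float
    cd4_sd: float
    lymph_node_prob: float = Field(ge=0, le=1)


class CohortConfig(BaseModel):
    """Generator parameters; defaults reproduce the reference cohort."""

    model_config = ConfigDict(frozen=True)

    seed: int = DEFAULT_SEED
    n_per_stage: tuple[int, int, int, int] = (0, 37, 14, 17)
    covariates: dict[int, _StageCovariates] = Field(
        default_factory=lambda: {
            1: _StageCovariates(
                age_mean_years=5.0, age_sd_years=2.0, cd4_mean=600.0,
                cd4_sd=150.0, lymph_node_prob=0.0,
            ),
            2: _StageCovariates(
                age_mean_years=6.0, age_sd_years=2.2, cd4_mean=450.0,
                cd4_sd=140.0, lymph_node_prob=19 / 23,  # ~30/37, enriched
            ),
            3: _StageCovariates(
                age_mean_years=12.6, age_sd_years=2.0, cd4_mean=380.0,
                cd4_sd=120.0, lymph_node_prob=3 / 14,
            ),
            4: _StageCovariates(
                age_mean_years=8.5, age_sd_years=2.8, cd4_mean=120.0,
                cd4_sd=60.0, lymph_node_prob=6 / 17,
            ),
        }
    )
    #: Stage-2 cART-at-diagnosis prevalence (realized as an exact count).
    stage2_cart_prob: float = 19 / 37
    #: Moderate-severe cytopenia prevalence among stage-2 patients not on
    #: cART (realized as an exact count).
    stage2_cytopenia_prob: float = 13 / 18
    #: Of the stage-3 patients, how many carry substage-A (<10% BSA) edema;
    #: the four complete-remission patients are all substage A. None derives
    #: min(5, n_stage3).
    stage3_n_substage_a: Optional[int] = None
    #: Of the stage-4 patients, how many have visceral involvement; the
    #: remainder present disseminated skin/oral disease without viscera.
    #: None derives min(9, n_stage4).
    stage4_n_visceral: Optional[int] = None
    outcome_mode: str = "frozen"  # "frozen" | "exponential"
    #: Monthly event hazards per stage for the exponential mode (NOT
    #: calibrated to the printed survival values).
    exponential_os_rate: dict[int, float] = Field(
        default_factory=lambda: {1: 0.002, 2: 0.012, 3: 0.012, 4: 0.25}
    )

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if any(n < 0 for n in self.n_per_stage):
            raise ValueError("per-stage n must be nonnegative")
        if self.outcome_mode not in ("frozen", "exponential"):
            raise ValueError("outcome_mode must be 'frozen' or 'exponential'")
        n3, n4 = self.n_per_stage[2], self.n_per_stage[3]
        if self.stage3_n_substage_a is not None and not (
            0 <= self.stage3_n_substage_a <= n3
        ):
            raise ValueError(
                f"stage3_n_substage_a={self.stage3_n_substage_a} incompatible "
                f"with {n3} stage-3 patients"
            )
        if self.stage4_n_visceral is not None and not (
            0 <= self.stage4_n_visceral <= n4
        ):
            raise ValueError(
                f"stage4_n_visceral={self.stage4_n_visceral} incompatible "
                f"with {n4} stage-4 patients"
            )
        return self

    @property
    def n_substage_a(self) -> int:
        """Effective stage-3 substage-A count."""
        if self.stage3_n_substage_a is not None:
            return self.stage3_n_substage_a
        return min(5, self.n_per_stage[2])

    @property
    def n_visceral(self) -> int:
        """Effective stage-4 visceral count."""
        if self.stage4_n_visceral is not None:
            return self.stage4_n_visceral
        return min(9, self.n_per_stage[3])


def build_outcome_tables(config: CohortConfig) -> dict[int, list[_OutcomeRow]]:
    """Per-stage outcome rows (row i pairs with patient i of that stage).

    With the default per-stage sample sizes the frozen tables are returned
    after :func:`validate_outcome_tables` re-checks every constraint; other
    sizes cycle the frozen rows (the product-limit calibration then no
    longer applies). Exponential mode draws times from per-stage hazards.
    """
    tables: dict[int, list[_OutcomeRow]] = {}
    if config.outcome_mode == "exponential":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
        for stage, n in zip((1, 2, 3, 4), config.n_per_stage):
            rate = config.exponential_os_rate[stage]
            times = rng.exponential(1.0 / rate, size=n)
            fu = rng.uniform(15.0, 50.0, size=n)
            rows = []
            for t, f in zip(times, fu):
                if t <= f:
                    rows.append(
                        _OutcomeRow(t, True, t, True, CauseOfDeath.KS)
                    )
                else:
                    rows.append(_alive(round(float(f), 1)))
            tables[stage] = rows
        return tables

    for stage, n in zip((1, 2, 3, 4), config.n_per_stage):
        if stage == 1:
            rows = [_alive(_STAGE1_FU[i % len(_STAGE1_FU)]) for i in range(n)]
        else:
            frozen = _FROZEN_ROWS[stage]
            rows = [frozen[i % len(frozen)] for i in range(n)]
        tables[stage] = rows
    if tuple(config.n_per_stage) == (0, 37, 14, 17):
        validate_outcome_tables(tables)
    return tables


def _km_at_24(rows: Sequence[_OutcomeRow], endpoint: str) -> float:
    if endpoint == "efs":
        times = [r.efs_time for r in rows]
        events = [r.efs_event for r in rows]
    else:
        times = [r.os_time for r in rows]
        events = [r.os_event for r in rows]
    return survival_at(km_fit(times, events), 24.0)


def validate_outcome_tables(tables: dict[int, list[_OutcomeRow]]) -> None:
    """Check the frozen tables against every printed-number constraint.

    Raises ``ValueError`` naming the first violated constraint. Product-
    limit values are recomputed with :func:`~lilongwe_ks.survival.km_fit`.
    """

    def require(cond: bool, label: str) -> None:
        if not cond:
            raise ValueError(f"outcome-table constraint violated: {label}")

    s2, s3, s4 = tables[2], tables[3], tables[4]
    require(len(s2) == 37, "stage 2 has 37 patients")
    require(len(s3) == 14, "stage 3 has 14 patients")
    require(len(s4) == 17, "stage 4 has 17 patients")
    for stage, rows in tables.items():
        for r in rows:
            require(r.efs_time <= r.os_time, f"stage {stage}: efs_time <= os_time")

    require(abs(_km_at_24(s2, "efs") - 27 / 37) < 1e-12, "stage-2 EFS(24) = 27/37")
    require(abs(_km_at_24(s2, "os") - 0.75) < 1e-12, "stage-2 OS(24) = 75%")
    require(abs(_km_at_24(s3, "efs") - 4 / 14) < 1e-12, "stage-3 EFS(24) = 4/14")
    require(abs(_km_at_24(s3, "os") - 11 / 14) < 1e-12, "stage-3 OS(24) = 11/14")
    require(_km_at_24(s4, "efs") == 0.0, "stage-4 EFS(24) = 0")
    require(abs(_km_at_24(s4, "os") - 2 / 17) < 1e-12, "stage-4 OS(24) = 2/17")

    deaths2 = [r for r in s2 if r.os_event]
    require(len(deaths2) == 10, "stage 2 has 10 deaths")
    require(
        sum(r.cause is CauseOfDeath.KS for r in deaths2) == 4,
        "stage 2: 4 KS deaths",
    )
    first_death2 = min(r.os_time for r in deaths2)
    require(
        sum(1 for r in s2 if not r.os_event and r.os_time < first_death2) == 1,
        "stage 2: one subject censored before the first death",
    )
    deaths3 = [r for r in s3 if r.os_event]
    require(len(deaths3) == 4, "stage 3 has 4 deaths")
    require(
        all(r.cause is not CauseOfDeath.KS for r in deaths3),
        "stage 3: all deaths non-KS",
    )
    require(
        sum(r.os_time <= 24 for r in deaths3) == 3,
        "stage 3: three deaths before month 24",
    )
    deaths4 = [r for r in s4 if r.os_event]
    require(len(deaths4) == 15, "stage 4 has 15 deaths")
    require(
        all(r.cause is CauseOfDeath.KS for r in deaths4),
        "stage 4: all deaths from KS",
    )
    pre_dox = sorted(r.os_time for r in deaths4 if r.regimen is Regimen.BV)
    require(len(pre_dox) == 12, "stage 4: 12 pre-doxorubicin deaths")
    require(
        float(np.median(pre_dox)) == 3.0,
        "stage 4: median pre-doxorubicin time to death = 3 months",
    )
    require(max(pre_dox) == 7.0, "stage 4: longest pre-doxorubicin survival = 7 months")
    abv_alive = sorted(
        r.os_time for r in s4 if not r.os_event and r.regimen is Regimen.ABV
    )
    require(abv_alive == [17.0, 27.0], "stage 4: survivors alive at 17 and 27 months")

    fu = sorted(
        r.os_time for rows in tables.values() for r in rows if not r.os_event
    )
    require(min(fu) >= 15.0 and max(fu) <= 50.0, "survivor follow-up within [15, 50]")
    require(float(np.median(fu)) == 28.0, "median survivor follow-up = 28 months")


# ---------------------------------------------------------------------------
# covariate and lesion generation


def _exact_count_mask(rng: np.random.Generator, n: int, prob: float) -> np.ndarray:
    """Boolean mask with exactly round(prob * n) True entries, placed at random."""
    count = int(round(prob * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=count, replace=False)] = True
    return mask


def _ages(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Ages with the sample mean recentred exactly to *mean*, kept in (0, 18)."""
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([mean])
    for _ in range(1000):
        dev = rng.normal(0.0, sd, size=n)
        dev -= dev.mean()
        ages = mean + dev
        if np.all((ages > 0.25) & (ages < 17.75)):
            return np.round(ages, 2) - (np.round(ages, 2).mean() - mean)
    raise ValueError(
        f"could not draw {n} ages with mean {mean} inside the pediatric range"
    )


def _cd4(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    return np.round(np.maximum(rng.normal(mean, sd, size=n), 5.0), 0)


def _skin_lesions(
    rng: np.random.Generator,
    count: int,
    regions: Sequence[Region],
    cluster: Optional[tuple[str, Region, int]] = None,
) -> list[Lesion]:
    """*count* cluster-collapsed hyperpigmented skin lesions over *regions*.

    With *cluster* = (id, region, extra), one of the counted lesions is a
    confluent cluster carrying *extra* additional member lesions — the
    collapsed tally is unchanged.
    """
    lesions = [
        Lesion(
            lesion_type=LesionType.HYPERPIGMENTED_SKIN,
            region=regions[i % len(regions)],
            longest_diameter_mm=float(np.round(rng.uniform(3, 25), 1)),
        )
        for i in range(count)
    ]
    if cluster is not None and count > 0:
        cid, region, extra = cluster
        clustered = [
            Lesion(
                lesion_type=LesionType.HYPERPIGMENTED_SKIN,
                region=region,
                cluster_id=cid,
                longest_diameter_mm=float(np.round(rng.uniform(3, 25), 1)),
            )
            for _ in range(extra + 1)
        ]
        lesions = lesions[:-1] + clustered
    return lesions


def _oral(rng: np.random.Generator, count: int, nodular: bool) -> list[Lesion]:
    lt = LesionType.NODULAR_ORAL if nodular else LesionType.FLAT_ORAL
    return [
        Lesion(
            lesion_type=lt,
            region=Region.ORAL_CAVITY,
            longest_diameter_mm=float(np.round(rng.uniform(2, 15), 1)),
        )
        for _ in range(count)
    ]


def _pick_regions(rng: np.random.Generator, k: int) -> list[Region]:
    idx = rng.choice(len(_CUTANEOUS), size=k, replace=False)
    return [_CUTANEOUS[i] for i in sorted(idx)]


def _stage1_lesions(rng: np.random.Generator) -> list[Lesion]:
    n_skin = int(rng.integers(2, 7))
    lesions = _skin_lesions(rng, n_skin, _pick_regions(rng, 2))
    if rng.random() < 0.4:
        lesions += _oral(rng, 1, nodular=False)
    if rng.random() < 0.3:
        lesions.append(
            Lesion(
                lesion_type=LesionType.SUBCUTANEOUS_NODULE,
                region=_CUTANEOUS[int(rng.integers(len(_CUTANEOUS)))],
                longest_diameter_mm=float(np.round(rng.uniform(5, 20), 1)),
            )
        )
    return lesions  # <= 8 lesions of stage-1 types


def _stage2_features(
    rng: np.random.Generator, lymph_node: bool
) -> tuple[list[Lesion], bool]:
    """Lesions + facial-edema flag guaranteeing stage 2 and nothing higher."""
    facial = False
    if lymph_node:
        # lymphadenopathic presentation, sparse skin disease
        lesions = _skin_lesions(rng, int(rng.integers(0, 9)), _pick_regions(rng, 2))
        if rng.random() < 0.25:
            lesions += _oral(rng, 1, nodular=bool(rng.random() < 0.5))
    else:
        trigger = rng.choice(
            ["hyper_10_19", "nodular_oral", "facial_edema", "conjunctival", "exophytic"]
        )
        if trigger == "hyper_10_19":
            count = int(rng.integers(10, 20))
            cluster = None
            if rng.random() < 0.3:
                region = _CUTANEOUS[int(rng.integers(len(_CUTANEOUS)))]
                cluster = (f"c{int(rng.integers(1e6))}", region, int(rng.integers(2, 6)))
            lesions = _skin_lesions(
                rng, count, _pick_regions(rng, int(rng.integers(2, 5))), cluster
            )
        elif trigger == "nodular_oral":
            lesions = _oral(rng, int(rng.integers(1, 3)), nodular=True)
            lesions += _skin_lesions(rng, int(rng.integers(0, 6)), _pick_regions(rng, 2))
        elif trigger == "facial_edema":
            facial = True
            lesions = _skin_lesions(rng, int(rng.integers(0, 6)), _pick_regions(rng, 2))
        elif trigger == "conjunctival":
            lesions = [
                Lesion(lesion_type=LesionType.CONJUNCTIVAL, region=Region.CONJUNCTIVA)
            ] + _skin_lesions(rng, int(rng.integers(0, 6)), _pick_regions(rng, 2))
        else:
            lesions = [
                Lesion(
                    lesion_type=LesionType.EXOPHYTIC_MASS,
                    region=_CUTANEOUS[int(rng.integers(len(_CUTANEOUS)))],
                    longest_diameter_mm=float(np.round(rng.uniform(20, 60), 1)),
                )
            ] + _skin_lesions(rng, int(rng.integers(0, 6)), _pick_regions(rng, 2))
    return lesions, facial


def _stage3_edema(rng: np.random.Generator, substage_a: bool) -> EdemaMap:
    leg = Region.LEFT_LEG if rng.random() < 0.5 else Region.RIGHT_LEG
    if substage_a:
        # localized, e.g. anterior inner thigh: well under 10% BSA
        frac = float(np.round(rng.uniform(0.2, 0.5), 2))  # 3.6–9.0% of BSA
        fractions = {leg: frac}
    else:
        fractions = {leg: 1.0}  # 18% BSA
        if rng.random() < 0.5:
            other = Region.RIGHT_LEG if leg is Region.LEFT_LEG else Region.LEFT_LEG
            fractions[other] = float(np.round(rng.uniform(0.3, 1.0), 2))
    return EdemaMap(fractions=fractions, woody=True)


def _stage4_features(
    rng: np.random.Generator, visceral: bool
) -> tuple[list[Lesion], bool, bool, EdemaMap]:
    """Lesions, visceral flags and edema for one stage-4 patient."""
    if visceral:
        pulm = bool(rng.random() < 0.6)
        abdo = (not pulm) or bool(rng.random() < 0.3)
        lesions = _skin_lesions(
            rng, int(rng.integers(3, 15)), _pick_regions(rng, int(rng.integers(1, 4)))
        )
        # oral involvement enriched in stage 4
        if rng.random() < 0.7:
            lesions += _oral(rng, int(rng.integers(1, 4)), nodular=bool(rng.random() < 0.5))
        edema = (
            _stage3_edema(rng, substage_a=False)
            if rng.random() < 0.2
            else EdemaMap()
        )
        return lesions, pulm, abdo, edema
    # disseminated skin/oral disease without viscera: >= 20 hyperpigmented
    # lesions over >= 4 regions; no woody edema, no nodular oral lesions,
    # so the ACTG T axis reads T0
    count = int(rng.integers(20, 27))
    cluster = None
    if rng.random() < 0.3:
        region = _CUTANEOUS[int(rng.integers(len(_CUTANEOUS)))]
        cluster = (f"c{int(rng.integers(1e6))}", region, int(rng.integers(3, 8)))
    lesions = _skin_lesions(
        rng, count, _pick_regions(rng, int(rng.integers(4, 7))), cluster
    )
    if rng.random() < 0.7:
        lesions += _oral(rng, int(rng.integers(1, 4)), nodular=False)
    return lesions, False, False, EdemaMap()


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate one synthetic cohort; deterministic for a fixed config.

    Every record is validated and re-classified before it is returned: the
    latent stage used for generation must be recovered exactly by
    :func:`~lilongwe_ks.staging.classify_stage`.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    tables = build_outcome_tables(config)
    cohort: list[PatientRecord] = []
    pid = 0
    for stage, n in zip((1, 2, 3, 4), config.n_per_stage):
        if n == 0:
            continue
        cov = config.covariates[stage]
        ages = _ages(rng, n, cov.age_mean_years, cov.age_sd_years)
        cd4 = _cd4(rng, n, cov.cd4_mean, cov.cd4_sd)
        lymph = _exact_count_mask(rng, n, cov.lymph_node_prob)
        if stage == 2:
            on_cart = _exact_count_mask(rng, n, config.stage2_cart_prob)
            n_off = int(n - on_cart.sum())
            cyto_off = _exact_count_mask(rng, n_off, config.stage2_cytopenia_prob)
        else:
            on_cart = rng.random(n) < 0.4
            cyto_off = None
        off_idx = 0
        for i in range(n):
            pid += 1
            row = tables[stage][i]
            facial = False
            pulm = abdo = False
            edema = EdemaMap()
            if stage == 1:
                lesions = _stage1_lesions(rng)
                regimen: Regimen = Regimen.CART_ONLY
            elif stage == 2:
                lesions, facial = _stage2_features(rng, bool(lymph[i]))
                regimen = row.regimen
            elif stage == 3:
                lesions = _skin_lesions(
                    rng, int(rng.integers(0, 10)), _pick_regions(rng, 2)
                )
                edema = _stage3_edema(rng, substage_a=i < config.n_substage_a)
                regimen = row.regimen
            else:
                lesions, pulm, abdo, edema = _stage4_features(
                    rng, visceral=i < config.n_visceral
                )
                regimen = row.regimen
            if stage == 2:
                if on_cart[i]:
                    grade = (
                        CytopeniaGrade.MILD
                        if rng.random() < 0.3
                        else CytopeniaGrade.NONE
                    )
                else:
                    grade = (
                        CytopeniaGrade.MODERATE_SEVERE
                        if cyto_off[off_idx]
                        else (
                            CytopeniaGrade.MILD
                            if rng.random() < 0.5
                            else CytopeniaGrade.NONE
                        )
                    )
                    off_idx += 1
            else:
                u = rng.random()
                grade = (
                    CytopeniaGrade.MODERATE_SEVERE
                    if u < 0.2
                    else CytopeniaGrade.MILD
                    if u < 0.5
                    else CytopeniaGrade.NONE
                )
            record = PatientRecord(
                patient_id=f"P{pid:03d}",
                age_years=float(np.round(ages[i], 3)),
                on_cart_at_diagnosis=bool(on_cart[i]),
                cd4_count_cells_per_uL=float(cd4[i]),
                cytopenia_grade=grade,
                lesions=tuple(lesions),
                lymph_node_involvement=bool(lymph[i]),
                visceral_pulmonary=pulm,
                visceral_abdominal=abdo,
                edema=EdemaMap(
                    fractions=edema.fractions,
                    woody=edema.woody,
                    facial_edema=facial,
                )
                if facial
                else edema,
                regimen=regimen,
                outcome=OutcomeRecord(
                    efs_time_months=row.efs_time,
                    efs_event=row.efs_event,
                    os_time_months=row.os_time,
                    os_event=row.os_event,
                    cause_of_death=row.cause,
                ),
            )
            assigned = classify_stage(record)
            if assigned.stage.pooled != str(stage):
                raise RuntimeError(
                    f"generator invariant broken: patient {record.patient_id} "
                    f"latent stage {stage} classified as {assigned.stage.value}"
                )
            if stage == 3:
                want = "3A" if i < config.n_substage_a else "3B"
                if assigned.stage.value != want:
                    raise RuntimeError(
                        f"generator invariant broken: patient {record.patient_id} "
                        f"latent substage {want} classified as {assigned.stage.value}"
                    )
            cohort.append(record)
    return cohort


def reference_cohort(seed: int = DEFAULT_SEED) -> list[PatientRecord]:
    """The packaged 68-patient reference cohort (default config).

    All printed-number aggregates — stage counts, cART/cytopenia
    proportions, stage-3 mean age, and every Kaplan–Meier value — are
    invariant to *seed*; the seed only permutes which patient carries
    which covariate draw.
    """
    return generate_cohort(CohortConfig(seed=seed))
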