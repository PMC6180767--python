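"""Shared fixtures and independent oracles.

The oracles here are deliberately written from the prose rules rather than
by calling the package: a literal decision-table transcription of the
staging rules, and a from-scratch risk-set recomputation of the
product-limit estimator. They exist so the implementation can be checked
against something it does not share code with.
"""

from __future__ import annotations

import numpy as np
import pytest

from lilongwe_ks import (
    EdemaMap,
    Lesion,
    LesionType,
    OutcomeRecord,
    PatientRecord,
    Region,
    classify_cohort,
    reference_cohort,
)

# ---------------------------------------------------------------------------
# record builders


def make_outcome(**kwargs) -> OutcomeRecord:
    base = dict(
        efs_time_months=12.0, efs_event=False, os_time_months=12.0, os_event=False
    )
    base.update(kwargs)
    return OutcomeRecord(**base)


def make_patient(**kwargs) -> PatientRecord:
    base = dict(
        patient_id="T001",
        age_years=7.0,
        on_cart_at_diagnosis=False,
        outcome=make_outcome(),
    )
    base.update(kwargs)
    return PatientRecord(**base)


def skin_lesions(count: int, regions: list[Region] | None = None) -> list[Lesion]:
    regions = regions or [Region.ANTERIOR_TRUNK]
    return [
        Lesion(
            lesion_type=LesionType.HYPERPIGMENTED_SKIN,
            region=regions[i % len(regions)],
        )
        for i in range(count)
    ]


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def ref_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def ref_stages(ref_cohort):
    return classify_cohort(ref_cohort)


# ---------------------------------------------------------------------------
# brute-force staging decision table (independent transcription)

#: Exact-percent edema fraction maps for the small-world BSA grid. Each
#: entry uses binary-exact fractions times integer Rule-of-9s weights so
#: the weighted sum is bit-exact at the 10% substage boundary.
BSA_GRID: dict[float, dict[Region, float]] = {
    0.0: {},
    5.0: {Region.LEFT_ARM: 0.5, Region.PERINEUM: 0.5},  # 4.5 + 0.5
    9.9: {Region.HEAD_NECK: 1.0, Region.PERINEUM: 0.9},  # 9 + 0.9
    10.0: {Region.HEAD_NECK: 1.0, Region.PERINEUM: 1.0},  # 9 + 1
    15.0: {
        Region.LEFT_LEG: 0.5,  # 9
        Region.RIGHT_LEG: 0.25,  # 4.5
        Region.HEAD_NECK: 0.125,  # 1.125
        Region.PERINEUM: 0.375,  # 0.375
    },
}


def stage_oracle(
    *,
    visceral_pulmonary: bool,
    visceral_abdominal: bool,
    n_skin: int,
    widespread: bool,
    woody: bool,
    bsa_percent: float,
    n_nodular_oral: int,
    n_conjunctival: int,
    n_exophytic: int,
    n_subq: int,
    lymph_node: bool,
    facial_edema: bool,
) -> str:
    """Literal decision-table transcription of the four stage definitions."""
    hyper = n_skin + n_nodular_oral  # skin + oral, nodules excluded
    if visceral_pulmonary or visceral_abdominal or (hyper >= 20 and widespread):
        return "4"
    if woody:
        return "3A" if bsa_percent < 10.0 else "3B"
    only_mild_types = n_nodular_oral == 0 and n_conjunctival == 0 and n_exophytic == 0
    if (
        only_mild_types
        and (n_skin + n_subq) < 10
        and not lymph_node
        and not facial_edema
    ):
        return "1"
    return "2"


def build_grid_patient(
    *,
    visceral_pulmonary: bool,
    visceral_abdominal: bool,
    n_skin: int,
    widespread: bool,
    woody: bool,
    bsa_percent: float,
    n_nodular_oral: int,
    n_conjunctival: int,
    n_exophytic: int,
    n_subq: int,
    lymph_node: bool,
    facial_edema: bool,
) -> PatientRecord:
    """Realize one small-world grid point as a full patient record.

    The widespread adjudication uses the per-record override so the grid
    controls it exactly; region-count operationalization is tested
    separately.
    """
    lesions = skin_lesions(n_skin, [Region.ANTERIOR_TRUNK, Region.LEFT_ARM])
    lesions += [
        Lesion(lesion_type=LesionType.NODULAR_ORAL, region=Region.ORAL_CAVITY)
        for _ in range(n_nodular_oral)
    ]
    lesions += [
        Lesion(lesion_type=LesionType.CONJUNCTIVAL, region=Region.CONJUNCTIVA)
        for _ in range(n_conjunctival)
    ]
    lesions += [
        Lesion(lesion_type=LesionType.EXOPHYTIC_MASS, region=Region.LEFT_LEG)
        for _ in range(n_exophytic)
    ]
    lesions += [
        Lesion(lesion_type=LesionType.SUBCUTANEOUS_NODULE, region=Region.RIGHT_ARM)
        for _ in range(n_subq)
    ]
    return make_patient(
        lesions=tuple(lesions),
        visceral_pulmonary=visceral_pulmonary,
        visceral_abdominal=visceral_abdominal,
        lymph_node_involvement=lymph_node,
        widespread_distribution=widespread,
        edema=EdemaMap(
            fractions=BSA_GRID[bsa_percent] if woody else {},
            woody=woody,
            facial_edema=facial_edema,
        ),
    )


def iter_small_world_grid():
    """The exhaustive small-world grid of staging inputs."""
    for visc_p in (False, True):
        for visc_a in (False, True):
            for n_skin in (0, 5, 9, 10, 15, 19, 20, 30):
                for widespread in (False, True):
                    for woody, bsa in [(False, 0.0)] + [
                        (True, b) for b in BSA_GRID
                    ]:
                        for nodular in (0, 1):
                            for conj in (0, 1):
                                for exo in (0, 1):
                                    for subq in (0, 2):
                                        for lymph in (False, True):
                                            for facial in (False, True):
                                                yield dict(
                                                    visceral_pulmonary=visc_p,
                                                    visceral_abdominal=visc_a,
                                                    n_skin=n_skin,
                                                    widespread=widespread,
                                                    woody=woody,
                                                    bsa_percent=bsa,
                                                    n_nodular_oral=nodular,
                                                    n_conjunctival=conj,
                                                    n_exophytic=exo,
                                                    n_subq=subq,
                                                    lymph_node=lymph,
                                                    facial_edema=facial,
                                                )


# ---------------------------------------------------------------------------
# product-limit risk-set oracle (independent recomputation)


def km_oracle_at(times, events, t: float) -> float:
    """S(t) by direct risk-set recomputation, events before censorings."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    surv = 1.0
    for u in sorted(set(times[events])):
        if u > t:
            break
        n_at_risk = int(np.sum(times >= u))
        d = int(np.sum((times == u) & events))
        surv *= 1.0 - d / n_at_risk
    return surv


# ---------------------------------------------------------------------------
# two-group log-rank statistic (independent, for the permutation null)


def logrank_two_group_oracle(times, events, group2_mask) -> float:
    """Chi-square log-rank statistic for two groups, written from the
    classical O−E / hypergeometric-variance formulas."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    g2 = np.asarray(group2_mask, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for u in sorted(set(times[events])):
        at_risk = times >= u
        n = int(at_risk.sum())
        n2 = int((at_risk & g2).sum())
        d = int(((times == u) & events).sum())
        d2 = int(((times == u) & events & g2).sum())
        o_minus_e += d2 - d * n2 / n
        if n > 1:
            var += d * (n2 / n) * (1 - n2 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else o_minus_e**2 / var
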