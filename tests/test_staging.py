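"""The Lilongwe stage classifier: counting, widespread rule, precedence,
induction response, and agreement with the brute-force decision table."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lilongwe_ks import (
    EdemaMap,
    Lesion,
    LesionType,
    Region,
    Stage,
    assess_induction,
    classify_stage,
    count_lesions,
    is_widespread,
)

from conftest import (
    build_grid_patient,
    iter_small_world_grid,
    make_patient,
    skin_lesions,
    stage_oracle,
)


class TestCountLesions:
    def test_confluent_cluster_counts_once(self):
        lesions = [
            Lesion(
                lesion_type=LesionType.HYPERPIGMENTED_SKIN,
                region=Region.ANTERIOR_TRUNK,
                cluster_id="c1",
            )
            for _ in range(30)
        ]
        tally = count_lesions(lesions)
        assert tally.hyperpigmented_skin_oral == 1
        assert tally.total == 1

    def test_empty_inventory(self):
        tally = count_lesions([])
        assert tally.total == 0
        assert tally.hyperpigmented_skin_oral == 0

    def test_nodules_excluded_from_hyperpigmented_tally(self):
        lesions = skin_lesions(25, [Region.ANTERIOR_TRUNK, Region.LEFT_ARM]) + [
            Lesion(
                lesion_type=LesionType.SUBCUTANEOUS_NODULE, region=Region.LEFT_LEG
            )
            for _ in range(5)
        ]
        tally = count_lesions(lesions)
        assert tally.hyperpigmented_skin_oral == 25
        assert tally.subcutaneous_nodule == 5
        assert tally.total == 30

    def test_oral_lesions_count_toward_hyperpigmented_tally(self):
        lesions = [
            Lesion(lesion_type=LesionType.FLAT_ORAL, region=Region.ORAL_CAVITY),
            Lesion(lesion_type=LesionType.NODULAR_ORAL, region=Region.ORAL_CAVITY),
        ]
        assert count_lesions(lesions).hyperpigmented_skin_oral == 2

    def test_cluster_spanning_regions_rejected(self):
        lesions = [
            Lesion(
                lesion_type=LesionType.HYPERPIGMENTED_SKIN,
                region=Region.LEFT_ARM,
                cluster_id="c1",
            ),
            Lesion(
                lesion_type=LesionType.HYPERPIGMENTED_SKIN,
                region=Region.RIGHT_ARM,
                cluster_id="c1",
            ),
        ]
        with pytest.raises(ValueError, match="spans regions"):
            count_lesions(lesions)


class TestWidespread:
    def test_four_regions_is_widespread(self):
        lesions = skin_lesions(
            20,
            [
                Region.HEAD_NECK,
                Region.ANTERIOR_TRUNK,
                Region.LEFT_LEG,
                Region.RIGHT_LEG,
            ],
        )
        assert is_widespread(lesions)

    def test_single_region_is_not_widespread(self):
        assert not is_widespread(skin_lesions(20))

    def test_empty_and_override(self):
        assert not is_widespread([])
        assert is_widespread([], override=True)
        assert not is_widespread(skin_lesions(20, list(Region)[:5]), override=False)


class TestClassifyExamples:
    def test_lymphadenopathy_only_is_stage2(self):
        patient = make_patient(lymph_node_involvement=True)
        result = classify_stage(patient)
        assert result.stage is Stage.S2
        assert "lymph_node_involvement" in result.triggered_rules

    def test_full_leg_edema_with_lymph_nodes_is_3b(self):
        patient = make_patient(
            lymph_node_involvement=True,
            edema=EdemaMap(fractions={Region.LEFT_LEG: 1.0}, woody=True),
        )
        result = classify_stage(patient)
        assert result.stage is Stage.S3B
        assert result.bsa_percent == 18.0

    def test_visceral_dominates_edema_and_lesions(self):
        patient = make_patient(
            visceral_pulmonary=True,
            lesions=tuple(skin_lesions(5)),
            edema=EdemaMap(fractions={Region.LEFT_LEG: 1.0}, woody=True),
        )
        result = classify_stage(patient)
        assert result.stage is Stage.S4
        assert result.triggered_rules == ("visceral_pulmonary",)

    def test_seven_skin_lesions_is_stage1(self):
        assert classify_stage(make_patient(lesions=tuple(skin_lesions(7)))).stage is Stage.S1

    def test_twelve_lesions_is_stage2(self):
        result = classify_stage(make_patient(lesions=tuple(skin_lesions(12))))
        assert result.stage is Stage.S2
        assert "hyperpigmented_10_19" in result.triggered_rules

    def test_widespread_25_lesions_is_stage4_without_viscera(self):
        lesions = skin_lesions(
            25, [Region.HEAD_NECK, Region.ANTERIOR_TRUNK, Region.LEFT_LEG, Region.LEFT_ARM]
        )
        result = classify_stage(make_patient(lesions=tuple(lesions)))
        assert result.stage is Stage.S4
        assert "hyperpigmented_ge20_widespread" in result.triggered_rules

    def test_facial_edema_without_woody_edema_is_stage2(self):
        patient = make_patient(edema=EdemaMap(facial_edema=True))
        result = classify_stage(patient)
        assert result.stage is Stage.S2
        assert "facial_edema" in result.triggered_rules


def test_exhaustive_agreement_with_decision_table():
    """classify_stage matches the independent brute-force decision table on
    the full small-world cross product (~2.5e4 cases)."""
    mismatches = []
    count = 0
    for case in iter_small_world_grid():
        count += 1
        expected = stage_oracle(**case)
        got = classify_stage(build_grid_patient(**case)).stage.value
        if got != expected:
            mismatches.append((case, expected, got))
    assert count > 10_000
    assert not mismatches, mismatches[:5]


_any_patient = st.builds(
    lambda n_skin, regions, lymph, facial, woody, frac, nodular: make_patient(
        lesions=tuple(
            skin_lesions(n_skin, regions)
            + [Lesion(lesion_type=LesionType.NODULAR_ORAL, region=Region.ORAL_CAVITY)]
            * nodular
        ),
        lymph_node_involvement=lymph,
        edema=EdemaMap(
            fractions={Region.LEFT_LEG: frac} if woody else {},
            woody=woody,
            facial_edema=facial,
        ),
    ),
    n_skin=st.integers(0, 30),
    regions=st.lists(
        st.sampled_from(
            [Region.HEAD_NECK, Region.ANTERIOR_TRUNK, Region.LEFT_LEG, Region.LEFT_ARM]
        ),
        min_size=1,
        max_size=4,
        unique=True,
    ),
    lymph=st.booleans(),
    facial=st.booleans(),
    woody=st.booleans(),
    frac=st.floats(0.1, 1.0),
    nodular=st.integers(0, 2),
)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(patient=_any_patient)
def test_dominance_monotonicity(patient):
    """Visceral involvement forces stage 4; adding woody edema to any
    stage-1/2 record moves it to stage 3."""
    visceral = patient.model_copy(update={"visceral_abdominal": True})
    assert classify_stage(visceral).stage is Stage.S4

    base = classify_stage(patient).stage
    if base in (Stage.S1, Stage.S2):
        edematous = patient.model_copy(
            update={
                "edema": EdemaMap(
                    fractions={Region.RIGHT_LEG: 0.5},
                    woody=True,
                    facial_edema=patient.edema.facial_edema,
                )
            }
        )
        assert classify_stage(edematous).stage in (Stage.S3A, Stage.S3B)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    n_skin=st.integers(1, 30),
    cluster_size=st.integers(2, 10),
    lymph=st.booleans(),
)
def test_cluster_monotonicity(n_skin, cluster_size, lymph):
    """Merging same-region lesions into a confluent cluster never raises a
    tally and never promotes the stage toward stage 4."""
    region = Region.ANTERIOR_TRUNK
    loose = skin_lesions(n_skin, [region, Region.LEFT_ARM, Region.LEFT_LEG, Region.HEAD_NECK])
    clustered = loose[: max(0, n_skin - cluster_size)] + [
        Lesion(
            lesion_type=LesionType.HYPERPIGMENTED_SKIN,
            region=region,
            cluster_id="merged",
        )
        for _ in range(min(cluster_size, n_skin))
    ]
    t_loose = count_lesions(loose)
    t_clustered = count_lesions(clustered)
    assert t_clustered.hyperpigmented_skin_oral <= t_loose.hyperpigmented_skin_oral
    assert t_clustered.total <= t_loose.total

    order = ["1", "2", "3A", "3B", "4"]
    s_loose = classify_stage(
        make_patient(lesions=tuple(loose), lymph_node_involvement=lymph)
    ).stage
    s_clustered = classify_stage(
        make_patient(lesions=tuple(clustered), lymph_node_involvement=lymph)
    ).stage
    assert order.index(s_clustered.value) <= order.index(s_loose.value)


class TestInductionResponse:
    def test_all_lesions_above_90pct_reduction_succeeds(self):
        result = assess_induction([(20.0, 1.0), (30.0, 2.0)])
        assert not result.induction_failure
        assert result.reductions == pytest.approx((0.95, 2.8 / 3))

    def test_exactly_90pct_reduction_fails(self):
        assert assess_induction([(20.0, 2.0)]).induction_failure

    def test_any_growing_lesion_fails(self):
        assert assess_induction([(20.0, 1.0), (10.0, 12.0)]).induction_failure

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least one lesion"):
            assess_induction([])
        with pytest.raises(ValueError, match="positive"):
            assess_induction([(20.0, 0.0)])
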