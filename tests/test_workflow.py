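import numpy as np
import pytest

from tmtvbench import (
    Interaction,
    MaskVolume,
    NoComponentAtPointError,
    PETVolume,
    SeedBelowThresholdError,
    Session,
    VoxelGrid,
    add_lesion_at,
    apply_edit_mask,
    preselect,
    remove_component_at,
    run_workflow,
    scenario,
)


def _pet(values, spacing=(4, 4, 4)):
    values = np.asarray(values, dtype=np.float32)
    return PETVolume(VoxelGrid(values.shape, spacing), values)


@pytest.fixture
def two_lesion_state(two_sphere_pet):
    pet, big, small = two_sphere_pet
    return pet, preselect(pet, min_volume_cm3=0.0), big, small


class TestRemoveComponentAt:
    def test_removes_whole_component_only(self, two_lesion_state):
        pet, cs, big, small = two_lesion_state
        out = remove_component_at(cs, (60, 60, 60))
        assert len(out.components) == len(cs.components) - 1
        assert out.tmtv == pytest.approx(cs.tmtv - big.sum() * 0.064)

    def test_background_click_errors_and_leaves_state(self, two_lesion_state):
        pet, cs, *_ = two_lesion_state
        before = cs.tmtv
        with pytest.raises(NoComponentAtPointError):
            remove_component_at(cs, (4, 4, 4))
        assert cs.tmtv == before

    def test_removal_order_does_not_matter(self, two_lesion_state):
        pet, cs, *_ = two_lesion_state
        a = remove_component_at(remove_component_at(cs, (60, 60, 60)), (120, 120, 120))
        b = remove_component_at(remove_component_at(cs, (120, 120, 120)), (60, 60, 60))
        assert a.tmtv == b.tmtv == 0.0
        np.testing.assert_array_equal(a.mask.labels, b.mask.labels)

    def test_index_click_with_explicit_flag(self, two_lesion_state):
        pet, cs, big, _ = two_lesion_state
        out = remove_component_at(cs, (15, 15, 15), point_is_index=True)
        assert out.tmtv < cs.tmtv


class TestApplyEditMask:
    def test_disjoint_mask_is_identity(self, two_lesion_state):
        pet, cs, *_ = two_lesion_state
        empty = MaskVolume(pet.grid, np.zeros(pet.grid.shape, int))
        out = apply_edit_mask(cs, empty)
        assert out.tmtv == cs.tmtv

    def test_dumbbell_cut_through_neck_splits(self):
        values = np.zeros((15, 5, 5))
        values[2:5, 1:4, 1:4] = 8.0
        values[5:8, 2, 2] = 8.0  # neck
        values[8:11, 1:4, 1:4] = 8.0
        pet = _pet(values)
        cs = preselect(pet, min_volume_cm3=0.0)
        assert len(cs.components) == 1
        remove = np.zeros(pet.grid.shape, int)
        remove[5:8, :, :] = 1
        out = apply_edit_mask(cs, MaskVolume(pet.grid, remove))
        assert len(out.components) == 2
        assert out.tmtv == pytest.approx(cs.tmtv - 3 * pet.grid.voxel_volume_cm3)

    def test_sub_3cm3_fragments_survive_editing(self):
        values = np.zeros((10, 5, 5))
        values[1:9, 1:3, 1:3] = 8.0  # 32 voxels = 2.048 cm^3 at 4 mm
        pet = _pet(values)
        cs = preselect(pet, min_volume_cm3=0.0)
        remove = np.zeros(pet.grid.shape, int)
        remove[4:6, :, :] = 1
        out = apply_edit_mask(cs, remove=MaskVolume(pet.grid, remove))
        # both fragments are < 3 cm^3 but are retained
        assert len(out.components) == 2

    def test_grid_mismatch_rejected(self, two_lesion_state):
        from tmtvbench import GridMismatchError

        pet, cs, *_ = two_lesion_state
        other = MaskVolume(VoxelGrid((5, 5, 5), (4, 4, 4)), np.zeros((5, 5, 5), int))
        with pytest.raises(GridMismatchError):
            apply_edit_mask(cs, other)


class TestAddLesionAt:
    def test_adds_small_lesion_without_volume_threshold(self, two_sphere_pet):
        pet, big, small = two_sphere_pet
        cs = preselect(pet)  # small sphere excluded at 3 cm^3
        out = add_lesion_at(cs, pet, (120, 120, 120))
        assert out.tmtv == pytest.approx(cs.tmtv + small.sum() * 0.064)

    def test_seed_below_threshold_errors(self, two_sphere_pet):
        pet, *_ = two_sphere_pet
        cs = preselect(pet)
        with pytest.raises(SeedBelowThresholdError):
            add_lesion_at(cs, pet, (4, 4, 4))  # background SUV 1

    def test_seed_in_included_component_is_idempotent(self, two_sphere_pet):
        pet, *_ = two_sphere_pet
        cs = preselect(pet)
        out = add_lesion_at(cs, pet, (60, 60, 60))
        assert out.tmtv == cs.tmtv
        np.testing.assert_array_equal(out.binary, cs.binary)

    def test_remove_then_add_restores_exactly(self, two_sphere_pet):
        pet, *_ = two_sphere_pet
        cs = preselect(pet)
        removed = remove_component_at(cs, (60, 60, 60))
        restored = add_lesion_at(removed, pet, (60, 60, 60))
        np.testing.assert_array_equal(restored.binary, cs.binary)


class TestInteractionValidation:
    @pytest.mark.parametrize(
        "kind,stage", [("remove_click", 3), ("edit_mask", 1), ("add_seed", 2)]
    )
    def test_kind_stage_pairing_enforced(self, kind, stage):
        with pytest.raises(ValueError):
            Interaction(kind, stage, point_mm=(0, 0, 0), mask_path="x.nii.gz")

    def test_click_requires_point(self):
        with pytest.raises(ValueError):
            Interaction("remove_click", 1)


class TestRunWorkflow:
    def test_empty_session_gives_preselection_at_all_stages(self, two_sphere_pet):
        pet, big, _ = two_sphere_pet
        res = run_workflow(pet, Session())
        expected = big.sum() * 0.064
        assert all(v == pytest.approx(expected) for v in res.tmtv_by_stage.values())

    def test_stage_chain_invariants(self, two_sphere_pet):
        pet, *_ = two_sphere_pet
        session = Session(
            interactions=[
                Interaction("remove_click", 1, point_mm=(60, 60, 60)),
                Interaction("add_seed", 4, point_mm=(120, 120, 120)),
            ]
        )
        t = run_workflow(pet, session).tmtv_by_stage
        assert t["TMTV3"] <= t["TMTV2"] <= t["TMTV1"]
        assert t["TMTV4"] >= t["TMTV3"]

    def test_lenient_mode_logs_failures_and_continues(self, two_sphere_pet):
        pet, *_ = two_sphere_pet
        session = Session(
            interactions=[
                Interaction("remove_click", 1, point_mm=(4, 4, 4)),  # background
                Interaction("add_seed", 4, point_mm=(120, 120, 120)),
            ]
        )
        res = run_workflow(pet, session)
        assert [e["ok"] for e in res.log] == [False, True]

    def test_strict_mode_raises_first_failure(self, two_sphere_pet):
        pet, *_ = two_sphere_pet
        session = Session(interactions=[Interaction("remove_click", 1, point_mm=(4, 4, 4))])
        with pytest.raises(NoComponentAtPointError):
            run_workflow(pet, session, strict=True)

    def test_replay_is_deterministic(self):
        from tmtvbench import rasterize

        case = scenario("myocardium_edit")
        pet, *_ = rasterize(case.spec)
        a = run_workflow(pet, case.session)
        b = run_workflow(pet, case.session)
        assert a.tmtv_by_stage == b.tmtv_by_stage
        for stage in range(5):
            np.testing.assert_array_equal(
                a.stage_sets[stage].mask.labels, b.stage_sets[stage].mask.labels
            )


class TestSessionSerialization:
    def test_json_round_trip(self, tmp_path):
        session = Session(
            case_id="c1",
            reader_id="r1",
            suv_min=4.0,
            interactions=[
                Interaction("remove_click", 1, point_mm=(10.0, 20.0, 30.0), note="brain"),
                Interaction("add_seed", 4, point_mm=(1.0, 2.0, 3.0)),
            ],
        )
        session.save(tmp_path / "s.json")
        back = Session.load(tmp_path / "s.json")
        assert back.case_id == "c1" and back.suv_min == 4.0
        assert [i.to_dict() for i in back.interactions] == [
            i.to_dict() for i in session.interactions
        ]

    def test_in_memory_edit_masks_materialized(self, tmp_path):
        case = scenario("myocardium_edit")
        case.session.save(tmp_path / "s.json", mask_dir=tmp_path)
        back = Session.load(tmp_path / "s.json")
        (edit,) = [i for i in back.interactions if i.kind == "edit_mask"]
        assert edit.mask_path and (tmp_path / "s.json").exists()
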