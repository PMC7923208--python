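"""Posing, the strain formula, and the full study pipeline."""

import numpy as np
import pytest

from uclstrain import (
    FIBER_NAMES,
    Pose,
    SpecimenLandmarks,
    average_strain,
    build_frame,
    fit_sphere,
    pose_insertions,
    run_strain_study,
    strain_percent,
)
from uclstrain.errors import (
    IncompleteTableError,
    MissingReferencePoseError,
    NonpositiveReferenceLengthError,
)
from uclstrain.simulation import StrainResult, StrainTable

from conftest import random_rotation_matrix
from test_geometry import axis_angle_matrix


def toy_specimen(insertion=(0.0, 0.0, 10.0), origin=(-20.0, 0.0, 0.0)):
    """Hand-built single-geometry specimen: exact sphere cloud, all nine
    fibers share one origin/insertion pair, frame axes are axis-aligned."""
    center = np.array([0.0, 300.0, 0.0])
    cloud = center + 25.0 * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    origin = np.asarray(origin, float)
    insertion = np.asarray(insertion, float)
    fields = {}
    for name in (
        "act_proximal", "pct_proximal", "ab_ant_origin", "ab_post_origin",
        "pb_ant_origin", "pb_antcen_origin", "pb_postcen_origin", "pb_post_origin",
    ):
        fields[name] = origin.copy()
    for name in (
        "act_distal", "pct_distal", "ab_ant_insertion", "ab_post_insertion",
        "pb_ant_insertion", "pb_antcen_insertion", "pb_postcen_insertion", "pb_post_insertion",
    ):
        fields[name] = insertion.copy()
    return SpecimenLandmarks(
        specimen_id="toy",
        group="I",
        side="left",
        medial_epicondyle_tip=np.array([-20.0, 0.0, 0.0]),
        lateral_epicondyle_tip=np.array([20.0, 0.0, 0.0]),
        humeral_head_cloud=cloud,
        **fields,
    )


def rigidly_transform(landmarks, rot, shift):
    moved = landmarks.copy()
    for name, p in list(moved.attachment_items()):
        setattr(moved, name, rot @ p + shift)
    for name in ("medial_epicondyle_tip", "lateral_epicondyle_tip"):
        setattr(moved, name, rot @ getattr(moved, name) + shift)
    moved.humeral_head_cloud = moved.humeral_head_cloud @ rot.T + shift
    return moved


class TestStrainPercent:
    @pytest.mark.parametrize(
        "lt, lst, expected",
        [(50.0, 50.0, 0.0), (44.0, 40.0, 10.0), (36.0, 40.0, -10.0)],
    )
    def test_examples(self, lt, lst, expected):
        assert strain_percent(lt, lst) == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance(self):
        for a in (0.1, 3.0, 1e4):
            assert strain_percent(44.0 * a, 40.0 * a) == pytest.approx(10.0, rel=1e-12)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(NonpositiveReferenceLengthError):
            strain_percent(10.0, 0.0)


class TestPoseInsertions:
    def _frame(self, landmarks):
        sphere = fit_sphere(landmarks.humeral_head_cloud)
        return build_frame(
            sphere.center,
            landmarks.medial_epicondyle_tip,
            landmarks.lateral_epicondyle_tip,
            landmarks.side,
        )

    def test_reference_pose_is_identity(self, specimen):
        frame = self._frame(specimen)
        posed = pose_insertions(specimen, frame, Pose(90.0, 0.0))
        assert np.array_equal(posed["AB1"], specimen.ab_ant_insertion)
        assert np.array_equal(posed["ACT"], specimen.act_distal)

    def test_full_extension_matches_matrix_oracle(self, specimen):
        frame = self._frame(specimen)
        posed = pose_insertions(specimen, frame, Pose(0.0, 0.0))
        oracle_rot = axis_angle_matrix(frame.z_axis, -90.0)
        expected = oracle_rot @ (specimen.pct_distal - frame.origin) + frame.origin
        assert np.allclose(posed["PCT"], expected, atol=1e-9)

    @pytest.mark.parametrize("pose", [Pose(0, 10), Pose(30, 10), Pose(120, 0), Pose(120, 10)])
    def test_rigidity_of_ulnar_point_set(self, group1_specimen, pose):
        frame = self._frame(group1_specimen)
        ref = pose_insertions(group1_specimen, frame, Pose(90.0, 0.0))
        posed = pose_insertions(group1_specimen, frame, pose)
        names = list(ref)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                d0 = np.linalg.norm(ref[a] - ref[b])
                d1 = np.linalg.norm(posed[a] - posed[b])
                assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)


class TestRunStrainStudy:
    def test_zero_strain_at_reference_pose(self, specimen):
        table = run_strain_study(specimen)
        for fiber in table.fibers:
            assert table.strain(fiber, 90.0, 0.0) == 0.0

    def test_insertion_on_both_axes_never_strains(self):
        # the frame origin lies on both rotation axes: a fiber inserting
        # there is a fixed point of every pose
        table = run_strain_study(toy_specimen(insertion=(0.0, 0.0, 0.0)))
        assert all(r.strain_pct == pytest.approx(0.0, abs=1e-9) for r in table.results)

    def test_closed_form_single_fiber(self):
        # axis-aligned toy frame: z = (-1,0,0), x = (0,0,1), origin at 0
        origin = np.array([-20.0, 0.0, 0.0])
        insertion = np.array([0.0, 0.0, 10.0])
        table = run_strain_study(toy_specimen(insertion=insertion, origin=origin))
        lst = np.linalg.norm(insertion - origin)
        for pose in table.poses:
            flex_m = axis_angle_matrix([-1.0, 0.0, 0.0], pose.flexion_deg - 90.0)
            valg_m = axis_angle_matrix([0.0, 0.0, 1.0], pose.valgus_deg)
            expected = (np.linalg.norm(valg_m @ flex_m @ insertion - origin) - lst) / lst * 100
            got = table.strain("ACT", pose.flexion_deg, pose.valgus_deg)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_global_rigid_transform_leaves_strain_unchanged(self, specimen):
        rng = np.random.default_rng(11)
        rot = random_rotation_matrix(rng)
        shift = rng.uniform(-200, 200, size=3)
        base = run_strain_study(specimen)
        moved = run_strain_study(rigidly_transform(specimen, rot, shift))
        for r in base.results:
            assert moved.strain(
                r.fiber_name, r.pose.flexion_deg, r.pose.valgus_deg
            ) == pytest.approx(r.strain_pct, abs=1e-6)

    def test_uniform_scaling_leaves_strain_unchanged(self, group1_specimen):
        scaled = rigidly_transform(group1_specimen, 2.0 * np.eye(3), np.zeros(3))
        base = run_strain_study(group1_specimen)
        out = run_strain_study(scaled)
        for r in base.results:
            assert out.strain(
                r.fiber_name, r.pose.flexion_deg, r.pose.valgus_deg
            ) == pytest.approx(r.strain_pct, abs=1e-9)

    def test_grid_must_contain_reference_pose(self, group1_specimen):
        with pytest.raises(MissingReferencePoseError):
            run_strain_study(group1_specimen, flexion_grid=[0, 30], valgus_grid=[0])
        with pytest.raises(MissingReferencePoseError):
            run_strain_study(group1_specimen, flexion_grid=[90], valgus_grid=[10])
        with pytest.raises(MissingReferencePoseError):
            run_strain_study(group1_specimen, flexion_grid=[], valgus_grid=[0])

    def test_rotation_orders_agree_at_zero_valgus(self, group1_specimen):
        a = run_strain_study(group1_specimen, rotation_order="flexion_then_valgus")
        b = run_strain_study(group1_specimen, rotation_order="valgus_then_flexion")
        for fiber in a.fibers:
            for flex in (0.0, 30.0, 60.0, 90.0, 120.0):
                assert a.strain(fiber, flex, 0.0) == pytest.approx(
                    b.strain(fiber, flex, 0.0), abs=1e-12
                )

    def test_wide_and_long_views_agree(self, specimen):
        table = run_strain_study(specimen)
        long = table.to_frame()
        for valgus in (0.0, 10.0):
            wide = table.to_wide(valgus, decimals=1)
            for fiber in table.fibers:
                for flex in wide.columns:
                    cell = wide.loc[fiber, flex]
                    row = long[
                        (long.fiber == fiber)
                        & (long.flexion_deg == flex)
                        & (long.valgus_deg == valgus)
                    ]
                    assert cell == pytest.approx(round(row.strain_pct.iloc[0], 1), abs=1e-12)


class TestAverageStrain:
    @staticmethod
    def _table(strains_by_pose):
        results = [
            StrainResult(fiber, pose, 10.0, 10.0 * (1 + s / 100), s)
            for pose, strains in strains_by_pose.items()
            for fiber, s in zip(FIBER_NAMES, strains)
        ]
        return StrainTable(results, "manual", "I")

    def test_constant_and_arithmetic_mean(self):
        table = self._table(
            {Pose(90.0, 0.0): [5.0] * 9, Pose(0.0, 0.0): list(range(9))}
        )
        averages = average_strain(table)
        assert averages[Pose(90.0, 0.0)] == pytest.approx(5.0)
        assert averages[Pose(0.0, 0.0)] == pytest.approx(4.0)

    def test_reference_average_is_zero(self, specimen):
        averages = average_strain(run_strain_study(specimen))
        assert averages[Pose(90.0, 0.0)] == 0.0

    def test_incomplete_table_rejected(self):
        full = self._table({Pose(90.0, 0.0): [0.0] * 9, Pose(0.0, 0.0): [1.0] * 9})
        holed = StrainTable(
            [r for r in full.results if not (r.fiber_name == "PB4" and r.pose == Pose(0.0, 0.0))],
            "manual",
            "I",
        )
        with pytest.raises(IncompleteTableError):
            average_strain(holed)
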