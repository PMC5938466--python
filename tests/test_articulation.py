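"""Tests for the articulation standardization procedures.

The central scientific claims live here: standardization removes
arbitrary rigid motions (pose invariance), is idempotent, hits the
requested inter-structure angle exactly, and never alters
within-structure shape or handedness.
"""

import math
from itertools import combinations

import numpy as np
import pytest

import articulate3d as a3
from articulate3d import articulation
from conftest import pairwise_distances, signed_volumes, translated_pair


def random_rigid_motion(rng, coords):
    """Apply a random proper rotation + translation (independent oracle:
    built from scipy's quaternion sampler, not the package's primitive)."""
    from scipy.spatial.transform import Rotation as ScipyRotation

    R = ScipyRotation.random(rng=rng).as_matrix()
    t = rng.uniform(-4.0, 4.0, size=3)
    return coords @ R.T + t


def standardize_set(sset, angle):
    pair = translated_pair(sset)
    spec = sset.articulation_spec(angle)
    if sset.joint_type == "single":
        return a3.simple_rotation(pair, spec).split()
    return a3.double_rotation(pair, spec)


# ---------------------------------------------------------------------------
# ArticulationSpec validation


class TestArticulationSpec:
    def test_valid_single_and_double(self):
        assert a3.ArticulationSpec((10, 1, 17), (52, 19, 107), 90).joint_type == "single"
        assert a3.ArticulationSpec((1, 2, 3, 4), (1, 2, 3, 4), 45).joint_type == "double"

    @pytest.mark.parametrize(
        "r1, r2, angle",
        [
            ((1, 1, 2), (1, 2, 3), 90),       # duplicate role
            ((1, 2), (1, 2), 90),             # too few roles
            ((1, 2, 3), (1, 2, 3, 4), 90),    # mixed kinds
            ((1, 2, 3), (1, 2, 3), 361.0),    # angle out of range
            ((0, 2, 3), (1, 2, 3), 90),       # 1-based indices
        ],
    )
    def test_invalid_specs_rejected(self, r1, r2, angle):
        with pytest.raises(ValueError):
            a3.ArticulationSpec(r1, r2, angle)


# ---------------------------------------------------------------------------
# target-angle exactness


@pytest.mark.parametrize("angle", [0.0, 30.0, 45.0, 90.0, 135.0, 180.0])
@pytest.mark.parametrize("joint", ["single", "double"])
def test_target_angle_hit_within_microdegrees(angle, joint, single_set, double_set):
    sset = single_set if joint == "single" else double_set
    r1, r2 = standardize_set(sset, angle)
    measured = a3.measure_inter_axis_angles_deg(r1, r2, sset.articulation_spec(angle))
    np.testing.assert_allclose(measured, angle, atol=1e-6)


# ---------------------------------------------------------------------------
# pose invariance — the purpose of the method


@pytest.mark.parametrize("joint", ["single", "double"])
def test_pose_invariance_under_50_random_rigid_motions(joint, single_set, double_set):
    """Standardizing a rigidly re-posed specimen reproduces the
    standardization of the original, for 50 independent random motions
    per structure."""
    sset = single_set if joint == "single" else double_set
    rng = np.random.default_rng(77)
    spec = sset.articulation_spec(60.0)
    n_roles = len(sset.roles_1)

    ref1, ref2 = standardize_set(sset, 60.0)
    base1 = sset.data_1.specimen(0)
    base2 = sset.data_2.specimen(0)
    worst = 0.0
    for _ in range(50):
        m1 = random_rigid_motion(rng, base1)
        m2 = random_rigid_motion(rng, base2)
        pair = a3.StructurePair(
            a3.LandmarkArray(m1[:, :, None], ["x"]).copy(),
            a3.LandmarkArray(m2[:, :, None], ["x"]),
        )
        pair = a3.StructurePair(
            a3.translate(pair.data_1, sset.roles_1[0]),
            a3.translate(pair.data_2, sset.roles_2[0]),
        )
        if joint == "single":
            s1, s2 = a3.simple_rotation(pair, spec).split()
        else:
            s1, s2 = a3.double_rotation(pair, spec)
        dev = max(
            np.max(np.abs(s1.specimen(0) - ref1.specimen(0))),
            np.max(np.abs(s2.specimen(0) - ref2.specimen(0))),
        )
        worst = max(worst, dev)
    assert worst < 1e-6, f"max coordinate deviation {worst}"
    assert n_roles in (3, 4)


@pytest.mark.parametrize("joint", ["single", "double"])
def test_idempotence(joint, single_set, double_set):
    """Standardizing an already-standardized pair reproduces it."""
    sset = single_set if joint == "single" else double_set
    spec = sset.articulation_spec(90.0)
    r1, r2 = standardize_set(sset, 90.0)
    pair = a3.StructurePair(r1, r2)
    if joint == "single":
        q1, q2 = a3.simple_rotation(pair, spec).split()
    else:
        q1, q2 = a3.double_rotation(pair, spec)
    np.testing.assert_allclose(q1.coords, r1.coords, atol=1e-9)
    np.testing.assert_allclose(q2.coords, r2.coords, atol=1e-9)


# ---------------------------------------------------------------------------
# shape preservation


@pytest.mark.parametrize("joint", ["single", "double"])
def test_rigidity_and_chirality_through_full_pipeline(joint, single_set, double_set):
    sset = single_set if joint == "single" else double_set
    r1, r2 = standardize_set(sset, 45.0)
    quads = list(combinations(range(sset.data_1.landmark_count), 4))
    for i in range(sset.data_1.specimen_count):
        for before, after in ((sset.data_1, r1), (sset.data_2, r2)):
            b = before.specimen(i)
            a = after.specimen(i)
            np.testing.assert_allclose(
                pairwise_distances(a), pairwise_distances(b), atol=1e-9
            )
            q = quads[: math.comb(b.shape[0], 4)]
            vb = signed_volumes(b, q)
            va = signed_volumes(a, q)
            assert np.all(np.sign(va) == np.sign(vb)), "reflection introduced"


def test_ground_truth_recovery(single_set):
    """All specimens share one template, so all standardized outputs must
    coincide with the template configuration."""
    r1, r2 = standardize_set(single_set, 90.0)
    t1, t2 = single_set.standardized_truth(90.0)
    assert np.max(np.abs(r1.coords - t1[:, :, None])) < 1e-9
    assert np.max(np.abs(r2.coords - t2[:, :, None])) < 1e-9


# ---------------------------------------------------------------------------
# mirroring correction


class TestMirrorCorrect:
    AXIS = np.array([1.0, 0.0, 0.0])

    def test_identity_when_orient_already_positive_in_plane(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0.5, 0.8, 0.0], [1, 1, 1.0]])
        out = a3.mirror_correct(pts, self.AXIS, 2)
        np.testing.assert_allclose(out, pts, atol=1e-12)

    def test_diametrically_opposite_orient_is_half_turn(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0.5, -0.8, 0.0]])
        out = a3.mirror_correct(pts, self.AXIS, 2)
        expected = a3.rotate_points(
            a3.axis_angle_rotation(self.AXIS, math.pi), pts
        )
        np.testing.assert_allclose(out, expected, atol=1e-9)
        assert out[2, 1] > 0.0

    def test_50_random_axis_aligned_structures(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(6, 3)) * 2.0
            out = a3.mirror_correct(pts, self.AXIS, 4)
            assert abs(out[4, 2]) < 1e-9
            assert out[4, 1] > 0.0
            np.testing.assert_allclose(
                pairwise_distances(out), pairwise_distances(pts), atol=1e-9
            )

    def test_orient_on_axis_raises(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [1.0, 0.0, 0.0]])
        with pytest.raises(a3.DegenerateGeometryError):
            a3.mirror_correct(pts, self.AXIS, 2)


# ---------------------------------------------------------------------------
# quality report


class TestLandmarkQuality:
    def test_collinear_roles_flagged(self):
        cases = a3.make_degenerate_cases(seed=3)
        pair = cases["collinear_roles"]
        spec = a3.ArticulationSpec((1, 2, 3, 4), (1, 2, 3, 4), 45)
        report = a3.check_landmark_quality(pair, spec)
        kinds = {(f.structure, f.kind) for f in report.flags}
        assert (1, "collinear_roles") in kinds

    def test_coincident_axis_pair_flagged(self):
        cases = a3.make_degenerate_cases(seed=3)
        pair = cases["coincident_axis_pair"]
        spec = a3.ArticulationSpec((1, 2, 3, 4), (1, 2, 3, 4), 45)
        report = a3.check_landmark_quality(pair, spec)
        assert any(f.kind == "coincident_axis_pair" and f.structure == 1
                   for f in report.flags)

    def test_well_spread_roles_give_empty_report(self, single_pair, single_set):
        report = a3.check_landmark_quality(
            single_pair, single_set.articulation_spec(90)
        )
        assert report.is_empty
        assert "no landmark-quality problems" in report.summary()
        # informational shared-coordinate deviations recorded regardless
        assert len(report.shared_coordinate_deviation) == 2 * single_set.data_1.specimen_count


# ---------------------------------------------------------------------------
# error paths


class TestErrorPaths:
    def test_untranslated_input_rejected_with_guidance(self, single_set):
        spec = single_set.articulation_spec(90)
        with pytest.raises(ValueError, match="translate"):
            a3.simple_rotation(single_set.pair, spec)

    def test_degenerate_geometry_names_specimen_and_structure(self):
        cases = a3.make_degenerate_cases(seed=5)
        pair = cases["orient_on_axis"]
        spec = a3.ArticulationSpec((1, 2, 3), (1, 2, 3), 90)
        with pytest.warns(UserWarning):  # quality warning precedes the error
            with pytest.raises(a3.DegenerateGeometryError, match="'d1'.*structure 1"):
                a3.simple_rotation(pair, spec)

    def test_coincident_axis_raises_degenerate_error(self):
        cases = a3.make_degenerate_cases(seed=5)
        pair = cases["coincident_axis_pair"]
        spec = a3.ArticulationSpec((1, 2, 3), (1, 2, 3), 90)
        with pytest.warns(UserWarning):
            with pytest.raises(a3.DegenerateGeometryError, match="coincide"):
                a3.simple_rotation(pair, spec)

    def test_reflected_specimen_raises_reflection_error(self):
        cases = a3.make_degenerate_cases(seed=5)
        pair = cases["reflected"]
        spec = a3.ArticulationSpec((1, 2, 3, 4), (1, 2, 3, 4), 45)
        with pytest.raises(a3.ReflectionError, match="d2"):
            a3.double_rotation(pair, spec)

    def test_unmatched_specimens_dropped_with_warning(self, rng, single_set):
        spec = single_set.articulation_spec(90)
        pair = translated_pair(single_set)
        d1 = pair.data_1
        # second dataset missing the last specimen, plus an extra one
        keep = d1.specimen_ids[:-1]
        extra = a3.LandmarkArray(
            np.concatenate(
                [pair.data_2.subset(keep).coords,
                 pair.data_2.coords[:, :, :1] + 0.0],
                axis=2,
            ),
            keep + ["extra"],
        )
        with pytest.warns(UserWarning, match="dropped"):
            joined = a3.simple_rotation((d1, extra), spec)
        assert joined.specimen_ids == keep


# ---------------------------------------------------------------------------
# offset


class TestOffsetStructure:
    def test_zero_offset_is_identity(self, single_set):
        out = a3.offset_structure(single_set.data_1, 1, (0, 0, 0))
        np.testing.assert_array_equal(out.coords, single_set.data_1.coords)

    def test_anchor_displaced_by_exactly_the_offset(self, single_set):
        r1, r2 = standardize_set(single_set, 45.0)
        out = a3.offset_structure(r2, 1, (1.7, 0.1, 0.0))
        np.testing.assert_allclose(
            out.coords[0] - r2.coords[0],
            np.tile([[1.7], [0.1], [0.0]], (1, r2.specimen_count)),
            atol=1e-12,
        )

    def test_distances_preserved_for_any_offset(self, rng, single_set):
        out = a3.offset_structure(single_set.data_2, 3, rng.normal(size=3))
        for i in range(out.specimen_count):
            np.testing.assert_allclose(
                pairwise_distances(out.specimen(i)),
                pairwise_distances(single_set.data_2.specimen(i)),
                atol=1e-9,
            )

    def test_bad_anchor(self, single_set):
        with pytest.raises(IndexError):
            a3.offset_structure(single_set.data_1, 99, (1, 0, 0))


def test_measure_inter_axis_angles_matches_vector_angle(single_set):
    r1, r2 = standardize_set(single_set, 135.0)
    spec = single_set.articulation_spec(135.0)
    got = a3.measure_inter_axis_angles_deg(r1, r2, spec)
    for i in range(r1.specimen_count):
        v1 = r1.specimen(i)[1] - r1.specimen(i)[0]
        v2 = r2.specimen(i)[1] - r2.specimen(i)[0]
        assert got[i] == pytest.approx(
            math.degrees(articulation.geometry.vector_angle(v1, v2)), abs=1e-12
        )
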