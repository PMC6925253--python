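"""Geometry oracles for the collective-variable layer.

Closed-form cases are asserted exactly; quaternion orientations are checked
against a rotation-matrix oracle; invariance under global rigid motion is
verified numerically.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rockbundle.colvars import (
    AtomGroup,
    CVSpec,
    DegenerateGeometryError,
    apply_transform,
    com_distance,
    com_projection,
    cv_gradient,
    evaluate_cv,
    kabsch_align,
    orientation_angle,
    orientation_quaternion,
    pairwise_rmsd_map,
    radius_of_gyration,
    rmsd,
    _fd_gradient,
)
from conftest import random_rotation


def test_atom_group_validation():
    with pytest.raises(ValueError):
        AtomGroup(())
    with pytest.raises(ValueError):
        AtomGroup((1, 1))
    with pytest.raises(ValueError):
        AtomGroup((0, 1), weights=(1.0,))
    g = AtomGroup((3, 1))
    with pytest.raises(IndexError):
        g.validate(2)


class TestComDistance:
    def test_three_four_five(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert com_distance(AtomGroup((0,)), AtomGroup((1,)), coords) == 5.0

    def test_same_group_is_zero(self):
        coords = np.random.default_rng(0).normal(size=(4, 3))
        g = AtomGroup((0, 1, 2, 3))
        assert com_distance(g, g, coords) == 0.0

    def test_matches_longhand_centroids(self, rng):
        coords = rng.normal(size=(8, 3))
        ga, gb = AtomGroup((0, 1, 2, 3)), AtomGroup((4, 5, 6, 7))
        expected = np.linalg.norm(coords[:4].mean(axis=0) - coords[4:].mean(axis=0))
        assert com_distance(ga, gb, coords) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self, rng):
        coords = rng.normal(size=(6, 3))
        ga, gb = AtomGroup((0, 1)), AtomGroup((2, 3, 4, 5))
        assert com_distance(ga, gb, coords) == com_distance(gb, ga, coords)

    def test_single_atom_perturbation_bound(self, rng):
        # moving one atom by delta shifts the centroid by <= delta / |group|
        coords = rng.normal(size=(6, 3))
        ga, gb = AtomGroup((0, 1, 2, 3)), AtomGroup((4, 5))
        d0 = com_distance(ga, gb, coords)
        delta = 0.7
        coords2 = coords.copy()
        coords2[2] += delta * np.array([1.0, 0.0, 0.0])
        d1 = com_distance(ga, gb, coords2)
        assert abs(d1 - d0) <= delta / 4 + 1e-12


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(AtomGroup((0,)), np.ones((1, 3))) == 0.0

    def test_equilateral_triangle(self):
        a = 2.0
        coords = np.array(
            [[0.0, 0.0, 0.0], [a, 0.0, 0.0], [a / 2, a * np.sqrt(3) / 2, 0.0]]
        )
        rg = radius_of_gyration(AtomGroup((0, 1, 2)), coords)
        assert rg == pytest.approx(a / np.sqrt(3), abs=1e-12)

    def test_matches_direct_formula(self, rng):
        coords = rng.normal(size=(5, 3))
        rg = radius_of_gyration(AtomGroup(tuple(range(5))), coords)
        d = coords - coords.mean(axis=0)
        assert rg == pytest.approx(np.sqrt((d**2).sum(1).mean()), abs=1e-12)


class TestKabsch:
    def test_identity(self, rng):
        coords = rng.normal(size=(6, 3))
        R, t = kabsch_align(coords, coords, AtomGroup(tuple(range(6))))
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0.0, atol=1e-10)

    def test_recovers_known_rotation(self, rng):
        ref = rng.normal(size=(8, 3))
        R_true = random_rotation(rng)
        mobile = ref @ R_true.T + np.array([1.0, -2.0, 0.5])
        R, t = kabsch_align(mobile, ref, AtomGroup(tuple(range(8))))
        # aligning mobile onto ref must invert the applied rotation
        assert np.allclose(R, R_true.T, atol=1e-8)
        assert np.allclose(apply_transform(mobile, R, t), ref, atol=1e-8)

    def test_reflection_gives_proper_rotation(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(5, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        R, t = kabsch_align(mirrored, ref, AtomGroup(tuple(range(5))))
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        g = AtomGroup(tuple(range(5)))
        assert rmsd(mirrored, ref, g, g) > 0.1

    def test_collinear_raises(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            kabsch_align(line, line, AtomGroup(tuple(range(5))))


class TestRmsd:
    def test_identical_zero(self, rng):
        coords = rng.normal(size=(7, 3))
        g = AtomGroup(tuple(range(7)))
        assert rmsd(coords, coords, g, g) == pytest.approx(0.0, abs=1e-12)

    def test_translation(self, rng):
        coords = rng.normal(size=(7, 3))
        t = np.array([1.0, 2.0, -2.0])
        g = AtomGroup(tuple(range(7)))
        assert rmsd(coords + t, coords, g, g) == pytest.approx(0.0, abs=1e-10)
        assert rmsd(coords + t, coords, g, None) == pytest.approx(
            np.linalg.norm(t), abs=1e-12
        )

    def test_shape_mismatch_raises(self):
        g = AtomGroup((0,))
        with pytest.raises(ValueError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)), g)

    def test_self_fit_not_worse_than_other_fit(self, small_system):
        structure, refs = small_system
        b1 = structure.bundle_group(1)
        b2 = structure.bundle_group(2)
        r_self = rmsd(refs.if_coords, refs.of_coords, b1, b1)
        r_other = rmsd(refs.if_coords, refs.of_coords, b1, b2)
        assert r_self <= r_other + 1e-12

    def test_bundle_rmsd_equals_rocking_displacement(self, small_system):
        # with bundle 2 aligned (exact overlay), bundle-1 RMSD must equal the
        # raw displacement produced by the rocking rotation
        structure, refs = small_system
        b1 = structure.bundle_atoms(1)
        expected = np.sqrt(
            ((refs.if_coords[b1] - refs.of_coords[b1]) ** 2).sum(1).mean()
        )
        got = rmsd(
            refs.if_coords, refs.of_coords,
            structure.bundle_group(1), structure.bundle_group(2),
        )
        assert got == pytest.approx(expected, abs=1e-8)


class TestOrientation:
    def test_identity(self, rng):
        coords = rng.normal(size=(6, 3))
        g = AtomGroup(tuple(range(6)))
        q = orientation_quaternion(g, coords, coords)
        assert q[0] == pytest.approx(1.0, abs=1e-9)
        assert orientation_angle(g, coords, coords) == pytest.approx(0.0, abs=1e-6)

    def test_known_rotation_about_z(self, rng):
        ref = rng.normal(size=(6, 3))
        g = AtomGroup(tuple(range(6)))
        R = Rotation.from_euler("z", 30.0, degrees=True).as_matrix()
        assert orientation_angle(g, ref @ R.T, ref) == pytest.approx(30.0, abs=1e-6)
        q = orientation_quaternion(g, ref @ R.T, ref)
        axis = q[1:] / np.linalg.norm(q[1:])
        assert abs(axis[2]) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("angle", [5.0, 45.0, 90.0, 135.0, 179.0])
    def test_angle_vs_rotation_matrix_oracle(self, angle, rng):
        # acceptance-grade check: random axes, angle recovered to 1e-6
        for _ in range(20):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
            ref = rng.normal(size=(7, 3))
            got = orientation_angle(AtomGroup(tuple(range(7))), ref @ R.T, ref)
            assert got == pytest.approx(angle, abs=1e-6)

    def test_canonical_w_nonnegative(self, rng):
        ref = rng.normal(size=(5, 3))
        R = Rotation.from_euler("y", 170.0, degrees=True).as_matrix()
        q = orientation_quaternion(AtomGroup(tuple(range(5))), ref @ R.T, ref)
        assert q[0] >= 0.0
        assert np.linalg.norm(q) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_raises(self):
        line = np.outer(np.arange(5.0), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(DegenerateGeometryError):
            orientation_quaternion(AtomGroup(tuple(range(5))), line, line)

    def test_analytic_gradient_matches_fd(self, small_system, rng):
        structure, refs = small_system
        helix = structure.group(structure.helix_atoms(1))
        spec = CVSpec(kind="orientation_angle", group=helix, ref_coords=refs.of_coords)
        x = refs.if_coords + rng.normal(0, 0.05, refs.if_coords.shape)
        g_an = cv_gradient(spec, x)
        g_fd = _fd_gradient(spec, x)
        assert np.abs(g_an - g_fd).max() < 1e-6 * max(1.0, np.abs(g_fd).max())


class TestEvaluateDispatch:
    def test_rmsd_spec_on_reference_zero(self, small_system):
        structure, refs = small_system
        g = structure.bundle_group(1)
        spec = CVSpec(kind="rmsd", group=g, fit_group=g, ref_coords=refs.of_coords)
        assert evaluate_cv(spec, refs.of_coords) == pytest.approx(0.0, abs=1e-9)

    def test_com_distance_dispatch_identity(self, rng):
        coords = rng.normal(size=(6, 3))
        ga, gb = AtomGroup((0, 1, 2)), AtomGroup((3, 4, 5))
        spec = CVSpec(kind="com_distance", group=ga, group_b=gb)
        assert evaluate_cv(spec, coords) == com_distance(ga, gb, coords)

    def test_orientation_spec_recovers_rocking_angle(self, small_system):
        structure, refs = small_system
        helix = structure.group(structure.helix_atoms(1))  # moving bundle
        spec = CVSpec(
            kind="orientation_angle", group=helix, ref_coords=refs.of_coords
        )
        assert evaluate_cv(spec, refs.if_coords) == pytest.approx(
            refs.rocking_angle_deg, abs=1e-6
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            CVSpec(kind="torsion", group=AtomGroup((0,)))

    def test_spec_serialization_round_trip(self, small_system):
        structure, refs = small_system
        helix = structure.group(structure.helix_atoms(1))
        spec = CVSpec(
            kind="orientation_angle", group=helix, ref_coords=refs.of_coords,
            name="theta",
        )
        back = CVSpec.from_dict(spec.to_dict())
        assert back.kind == spec.kind
        assert back.group.indices == spec.group.indices
        assert evaluate_cv(back, refs.if_coords) == evaluate_cv(spec, refs.if_coords)


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("kind", ["com_distance", "radius_of_gyration", "rmsd"])
    def test_cv_invariance(self, kind, small_system, rng):
        structure, refs = small_system
        coords = refs.if_coords + rng.normal(0, 0.1, refs.if_coords.shape)
        ga = structure.bundle_group(1)
        gb = structure.bundle_group(2)
        if kind == "com_distance":
            spec = CVSpec(kind=kind, group=ga, group_b=gb)
        elif kind == "radius_of_gyration":
            spec = CVSpec(kind=kind, group=ga)
        else:
            spec = CVSpec(kind=kind, group=ga, fit_group=gb, ref_coords=refs.of_coords)
        v0 = evaluate_cv(spec, coords)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        assert evaluate_cv(spec, coords @ R.T + t) == pytest.approx(v0, abs=1e-8)

    def test_orientation_invariance_with_common_frame(self, small_system, rng):
        # rotating both the coordinates and the reference leaves the relative
        # orientation unchanged
        structure, refs = small_system
        helix = structure.group(structure.helix_atoms(1))
        R = random_rotation(rng)
        t = rng.normal(size=3)
        a0 = orientation_angle(helix, refs.if_coords, refs.of_coords)
        a1 = orientation_angle(
            helix, refs.if_coords @ R.T + t, refs.of_coords @ R.T + t
        )
        assert a1 == pytest.approx(a0, abs=1e-8)


class TestPairwiseRmsdMap:
    def test_constant_trajectory_zero(self, rng):
        frame = rng.normal(size=(6, 3))
        g = AtomGroup(tuple(range(6)))
        m = pairwise_rmsd_map([frame] * 4, g, g)
        assert np.allclose(m, 0.0, atol=1e-10)

    def test_two_frames_match_rmsd(self, rng):
        f0, f1 = rng.normal(size=(2, 6, 3))
        g = AtomGroup(tuple(range(6)))
        m = pairwise_rmsd_map([f0, f1], g, g)
        assert m[0, 1] == pytest.approx(rmsd(f0, f1, g, g), abs=1e-12)

    def test_symmetry(self, rng):
        frames = rng.normal(size=(5, 6, 3))
        g = AtomGroup(tuple(range(6)))
        m = pairwise_rmsd_map(list(frames), g, None)
        assert np.abs(m - m.T).max() < 1e-10
        assert np.allclose(np.diag(m), 0.0)

    def test_needs_two_frames(self, rng):
        g = AtomGroup((0, 1))
        with pytest.raises(ValueError):
            pairwise_rmsd_map([rng.normal(size=(2, 3))], g)


def test_com_projection_translation():
    coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    g = AtomGroup((0, 1))
    spec = CVSpec(kind="com_projection", group=g, axis=(1.0, 0.0, 0.0))
    assert evaluate_cv(spec, coords) == pytest.approx(1.0)
    assert evaluate_cv(spec, coords + [3.0, 0.0, 0.0]) == pytest.approx(4.0)
    grad = cv_gradient(spec, coords)
    assert np.allclose(grad[:, 0], 0.5)
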