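"""Rigid-body math and structural measurements against closed-form and
brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hybridem.geometry import (DomainRange, GeometryError, RigidTransform,
                               SasaParams, buried_area, domain_extent,
                               insert_anchor, interval_length, min_distance,
                               reach, rotation_angle, sasa, superpose)
from hybridem.structio import AtomRecord, StructureModel
from hybridem.synthetic import ideal_helix

from conftest import rmsd


def _random_rotation(rng):
    return Rotation.random(rng=rng).as_matrix()


def _carbon_model(xyz, start=1):
    return StructureModel([
        AtomRecord("A", start + i, "ALA", "CA", p, element="C")
        for i, p in enumerate(np.atleast_2d(xyz))
    ])


class TestSuperpose:
    def test_identity_on_self(self):
        pts = np.random.default_rng(0).uniform(-10, 10, (20, 3))
        res = superpose(pts, pts)
        assert res.rmsd < 1e-9
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_known_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-20, 20, (30, 3))
        rot, t = _random_rotation(rng), rng.uniform(-50, 50, 3)
        moved = pts @ rot.T + t
        res = superpose(moved, pts)
        assert res.rmsd < 1e-9
        assert rotation_angle(res.transform.rotation, rot.T) < 1e-4

    def test_reflection_never_returned(self):
        # mirror-image point sets force the unconstrained optimum to det −1
        rng = np.random.default_rng(2)
        pts = rng.uniform(-10, 10, (15, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        res = superpose(mirrored, pts)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_three_points_is_an_error(self):
        with pytest.raises(GeometryError, match="3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_sets_are_flagged(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        assert superpose(line, line).degenerate

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(-10, 10, (25, 3))
        b = a + rng.normal(0, 1.0, a.shape)
        base = superpose(a, b).rmsd
        for _ in range(100):
            rot, t = _random_rotation(rng), rng.uniform(-30, 30, 3)
            assert superpose(a @ rot.T + t, b @ rot.T + t).rmsd == pytest.approx(base, abs=1e-8)

    def test_idempotent_after_applying_solution(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-10, 10, (12, 3))
        b = rng.uniform(-10, 10, (12, 3))
        res = superpose(a, b)
        again = superpose(res.transform.apply(a), b)
        assert again.rmsd == pytest.approx(res.rmsd, abs=1e-9)
        assert rotation_angle(again.transform, RigidTransform()) < 1e-6


class TestRotationAngle:
    def test_identical_transforms_give_zero(self):
        t = RigidTransform.from_rotvec([10, 20, 30])
        assert rotation_angle(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_35_degree_rotation(self):
        axis = np.array([1.0, 2.0, -0.5])
        axis /= np.linalg.norm(axis)
        t = RigidTransform.from_rotvec(35.0 * axis)
        assert rotation_angle(RigidTransform(), t) == pytest.approx(35.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_trace_formula_and_is_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        ra, rb = _random_rotation(rng), _random_rotation(rng)
        rel = rb @ ra.T
        expected = np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        assert rotation_angle(ra, rb) == pytest.approx(expected, abs=1e-9)
        assert rotation_angle(rb, ra) == pytest.approx(expected, abs=1e-9)

    def test_triangle_inequality_over_composed_rotations(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c = (_random_rotation(rng) for _ in range(3))
            assert rotation_angle(a, c) <= rotation_angle(a, b) + rotation_angle(b, c) + 1e-9


class TestMinDistance:
    def test_shared_atom_gives_zero(self):
        m = _carbon_model([[0, 0, 0], [5, 0, 0]])
        assert min_distance(m, m).distance == 0.0

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(12)
        a = _carbon_model(rng.uniform(-30, 30, (50, 3)))
        b = _carbon_model(rng.uniform(-30, 30, (50, 3)))
        brute = min(np.linalg.norm(pa.position - pb.position)
                    for pa in a for pb in b)
        res = min_distance(a, b)
        assert res.distance == pytest.approx(brute, abs=1e-12)
        assert min_distance(b, a).distance == pytest.approx(brute, abs=1e-12)

    def test_empty_selection_error_names_side(self):
        m = _carbon_model([[0, 0, 0]])
        with pytest.raises(GeometryError, match="second"):
            min_distance(m, StructureModel())


class TestSasa:
    def test_isolated_carbon_matches_closed_form(self):
        m = _carbon_model([[0.0, 0.0, 0.0]])
        area = sasa(m, SasaParams()).sum()
        assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)

    def test_two_far_atoms_do_not_occlude(self):
        m = _carbon_model([[0, 0, 0], [100, 0, 0]])
        assert sasa(m).sum() == pytest.approx(2 * 4 * np.pi * 3.1 ** 2, rel=1e-6)

    @pytest.mark.parametrize("d", [2.0, 4.0, 5.5])
    def test_overlapping_equal_spheres_match_cap_formula(self, d):
        # two equal spheres radius R at distance d: exposed area per sphere
        # is 4πR² − 2πR·h with cap height h = R − d/2
        m = _carbon_model([[0, 0, 0], [d, 0, 0]])
        r = 3.1  # carbon 1.7 + probe 1.4
        expected = 2 * (4 * np.pi * r ** 2 - 2 * np.pi * r * (r - d / 2))
        assert sasa(m, SasaParams()).sum() == pytest.approx(expected, rel=0.02)

    def test_deterministic_across_reruns(self, manifest):
        m = manifest.target_model
        assert np.array_equal(sasa(m), sasa(m))

    def test_unknown_element_error_lists_atoms(self):
        m = StructureModel([AtomRecord("A", 1, "UNK", "XX", [0, 0, 0], element="XQ")])
        with pytest.raises(GeometryError, match="XX"):
            sasa(m)


class TestBuriedArea:
    def test_far_groups_bury_nothing(self):
        a = _carbon_model([[0, 0, 0], [3, 0, 0], [0, 3, 0]])
        b = _carbon_model([[200, 0, 0], [203, 0, 0], [200, 3, 0]], start=100)
        res = buried_area(StructureModel(a.atoms + b.atoms), a, b)
        assert res.total == pytest.approx(0.0, abs=1e-6)

    def test_two_sphere_toy_matches_cap_oracle(self):
        d, r = 4.0, 3.1
        a, b = _carbon_model([[0, 0, 0]]), _carbon_model([[d, 0, 0]], start=2)
        res = buried_area(StructureModel(a.atoms + b.atoms), a, b)
        expected_total = 2 * 2 * np.pi * r * (r - d / 2)  # both caps
        assert res.total == pytest.approx(expected_total, rel=0.02)
        assert res.one_sided == pytest.approx(res.total / 2)

    def test_symmetric_in_its_groups(self, manifest):
        model = manifest.target_model
        a = DomainRange("A", 1, 20)
        b = DomainRange("A", 21, 45)
        assert buried_area(model, a, b).total == pytest.approx(
            buried_area(model, b, a).total, abs=1e-9)

    def test_overlapping_groups_rejected(self, manifest):
        model = manifest.target_model
        with pytest.raises(GeometryError, match="overlap"):
            buried_area(model, DomainRange("A", 1, 10), DomainRange("A", 5, 15))


class TestShapeMeasures:
    def test_two_points_with_midpoint_give_length_50(self):
        pts = np.array([[0, 0, 0], [50, 0, 0], [25, 0, 0]], dtype=float)
        assert domain_extent(pts).length == pytest.approx(50.0, abs=1e-9)

    @pytest.mark.parametrize("n", [20, 40])
    def test_ideal_helix_length_tracks_rise(self, n):
        helix = ideal_helix(n, axis=(0.3, -0.5, 0.8))
        ext = domain_extent(helix)
        assert ext.length == pytest.approx(1.5 * (n - 1), rel=0.05)

    def test_collinear_cloud_is_flagged(self):
        line = np.outer(np.arange(10.0), [0.0, 1.0, 0.0])
        assert domain_extent(line).degenerate

    def test_reach_bounded_by_cloud_radius(self):
        rng = np.random.default_rng(3)
        cloud = rng.uniform(-5, 5, (30, 3))
        cloud = cloud[np.linalg.norm(cloud, axis=1) <= 5.0]
        assert reach(cloud, [0.0, 0.0, 0.0]) <= 5.0

    def test_reach_matches_exhaustive_scan(self):
        rng = np.random.default_rng(8)
        cloud = rng.uniform(-40, 40, (100, 3))
        anchor = rng.uniform(-10, 10, 3)
        brute = max(np.linalg.norm(p - anchor) for p in cloud)
        assert reach(cloud, anchor) == pytest.approx(brute, abs=1e-12)

    def test_reach_empty_selection_is_error(self):
        with pytest.raises(GeometryError):
            reach(np.zeros((0, 3)), [0, 0, 0])

    def test_insert_anchor_is_boundary_ca_midpoint(self, manifest):
        r = manifest.insert_ranges["insA"]
        model = manifest.target_model
        anchor = insert_anchor(model, "A", r.first_residue, r.last_residue)
        ca1 = model.residue_ca("A", r.first_residue).position
        ca2 = model.residue_ca("A", r.last_residue).position
        assert np.allclose(anchor, (ca1 + ca2) / 2)


class TestIntervalLength:
    @pytest.mark.parametrize("first,last,expected", [
        (938, 1042, 105),   # a 105-residue insert span
        (1122, 1180, 59),   # a 59-residue insert span
        (7, 7, 1),
    ])
    def test_inclusive_interval_arithmetic(self, first, last, expected):
        assert interval_length(DomainRange("A", first, last)) == expected

    def test_inverted_interval_is_an_error(self):
        with pytest.raises(GeometryError):
            DomainRange("A", 10, 9)
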