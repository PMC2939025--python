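"""Rigid placement, linker feasibility and flexible fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hybridem import synthetic
from hybridem.densityfit import (ENMParams, FitError, LinkerSpec, flexible_fit,
                                 linker_feasibility, model_map_cc,
                                 refine_placement, rigid_fit)
from hybridem.emmap import simulate_map
from hybridem.geometry import DomainRange, RigidTransform, rotation_angle
from hybridem.structio import AtomRecord, StructureModel

from conftest import rmsd


@pytest.fixture(scope="module")
def truth_map15(manifest):
    return simulate_map(manifest.target_model, 15.0, 2.0, 40)


class TestModelMapCC:
    def test_model_in_its_own_map_scores_near_one(self, manifest, truth_map):
        assert model_map_cc(manifest.target_model, truth_map, 10.0) > 0.999

    def test_shifted_model_scores_strictly_lower(self, manifest, truth_map):
        base = model_map_cc(manifest.target_model, truth_map, 10.0)
        shifted = manifest.target_model.transformed(
            RigidTransform(np.eye(3), np.array([6.0, 0.0, 0.0])))
        assert model_map_cc(shifted, truth_map, 10.0) < base

    def test_invariant_under_affine_map_rescaling(self, manifest, truth_map):
        base = model_map_cc(manifest.target_model, truth_map, 10.0)
        scaled = truth_map.copy()
        scaled.values = scaled.values * 5.0 + 3.0
        assert model_map_cc(manifest.target_model, scaled, 10.0) == \
            pytest.approx(base, abs=1e-6)

    def test_model_outside_bounds_reports_atom_count(self, manifest, truth_map):
        far = manifest.target_model.transformed(
            RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0])))
        with pytest.raises(FitError, match="atoms"):
            model_map_cc(far, truth_map, 10.0)


class TestLinkerFeasibility:
    def _pair(self, span):
        scaf = StructureModel([AtomRecord("A", 1, "GLY", "CA", [0.0, 0.0, 0.0])])
        frag = StructureModel([AtomRecord("A", 1, "GLY", "CA", [span, 0.0, 0.0])])
        return scaf, frag

    def test_zero_missing_short_span_is_feasible(self):
        scaf, frag = self._pair(3.0)
        spans, ok = linker_feasibility(scaf, frag, RigidTransform(),
                                       [LinkerSpec(1, 1, 0)])
        assert ok and spans == [pytest.approx(3.0)]

    def test_two_missing_long_span_is_infeasible(self):
        scaf, frag = self._pair(12.0)
        spans, ok = linker_feasibility(scaf, frag, RigidTransform(),
                                       [LinkerSpec(1, 1, 2)])
        assert not ok  # 12.0 > 3.8 × 3 = 11.4

    @pytest.mark.parametrize("seed", range(4))
    def test_flag_matches_brute_force_recomputation(self, manifest, seed):
        rng = np.random.default_rng(seed)
        scaf = manifest.target_model
        frag = DomainRange("A", 26, 45).select(manifest.target_model).copy()
        t = RigidTransform(Rotation.random(rng=rng).as_matrix(),
                           rng.uniform(-10, 10, 3))
        linkers = [LinkerSpec(25, 26, int(rng.integers(0, 4))),
                   LinkerSpec(46, 45, int(rng.integers(0, 4)))]
        spans, ok = linker_feasibility(scaf, frag, t, linkers)
        brute = []
        for lk in linkers:
            a = scaf.residue_ca("A", lk.scaffold_residue).position
            b = t.apply(frag.residue_ca("A", lk.fragment_residue).position[None])[0]
            brute.append(np.linalg.norm(a - b))
        assert np.allclose(spans, brute)
        assert ok == all(s <= 3.8 * (lk.missing_residues + 1)
                         for s, lk in zip(brute, linkers))

    def test_missing_anchor_is_an_error(self, manifest):
        frag = DomainRange("A", 26, 45).select(manifest.target_model)
        with pytest.raises(FitError, match="anchor"):
            linker_feasibility(manifest.target_model, frag, RigidTransform(),
                               [LinkerSpec(9999, 26, 0)])


class TestRigidFit:
    def test_local_refinement_keeps_the_true_placement(self, manifest):
        frag = manifest.insert_ranges["insA"].select(manifest.target_model)
        dmap = simulate_map(frag, 10.0, 2.0, 32)
        refined = refine_placement(frag, dmap, RigidTransform(), 10.0)
        assert rotation_angle(refined, RigidTransform()) < 2.0
        center = frag.coords().mean(axis=0)
        assert np.linalg.norm(refined.apply(center[None])[0] - center) < 1.0

    def test_coarse_search_recovers_displaced_fragment(self, manifest):
        # quick 30° version of the known-truth recovery (the 15° version
        # runs in the acceptance suite)
        frag = manifest.fragments["insA"]
        region = frag.splice_spec.insert_source.select(manifest.target_model)
        dmap = simulate_map(region, 10.0, 2.0, 32)
        res = rigid_fit(frag.model, dmap, 10.0, angular_step=30.0, n_refine=5)
        best = res.best
        assert rotation_angle(best.transform, frag.true_placement) < 10.0

    def test_two_lobe_disambiguation_leaves_one_feasible(self):
        fragment, scaffold, linkers, density = synthetic.make_two_lobe_fragment()
        res = rigid_fit(fragment, density, 10.0, angular_step=30.0,
                        scaffold=scaffold, linkers=linkers, n_refine=6)
        assert len(res.feasible) == 1
        assert res.infeasible  # the flipped orientation is found but rejected
        assert rotation_angle(res.feasible[0].transform, RigidTransform()) < 5.0
        flipped = [p for p in res.infeasible
                   if rotation_angle(p.transform, RigidTransform()) > 170.0]
        assert flipped and all(p.cc > 0.95 for p in flipped)

    def test_results_invariant_under_common_frame_shift(self, manifest):
        frag = manifest.insert_ranges["insA"].select(manifest.target_model).copy()
        dmap = simulate_map(frag, 10.0, 2.0, 24)
        res_a = rigid_fit(frag, dmap, 10.0, angular_step=45.0, n_refine=2)
        shift = np.array([17.0, -4.0, 9.0])
        moved = frag.transformed(RigidTransform(np.eye(3), shift))
        dmap_b = dmap.copy()
        dmap_b.origin = dmap_b.origin + shift
        res_b = rigid_fit(moved, dmap_b, 10.0, angular_step=45.0, n_refine=2)
        assert res_a.best.cc == pytest.approx(res_b.best.cc, abs=2e-3)
        assert rotation_angle(res_a.best.transform, res_b.best.transform) < 2.0


class TestFlexibleFit:
    def test_model_already_in_density_stays_put(self, manifest, truth_map15):
        fitted, diag = flexible_fit(manifest.target_model, truth_map15,
                                    resolution=15.0)
        assert rmsd(fitted.coords(), manifest.target_model.coords()) < 0.1
        assert diag.cc_final >= diag.cc_initial

    def test_freezing_everything_is_a_noop(self, manifest, truth_map15):
        freeze = manifest.target_model.residue_numbers()
        fitted, diag = flexible_fit(manifest.target_model, truth_map15,
                                    freeze=freeze, resolution=15.0)
        assert np.allclose(fitted.coords(), manifest.target_model.coords())
        assert diag.cc_final == diag.cc_initial

    def test_hinge_bend_recovery_halves_the_rmsd(self, manifest, truth_map15):
        truth = manifest.target_model
        r = manifest.insert_ranges["insA"]
        bent = truth.copy()
        hinge = truth.residue_ca("A", r.first_residue).position
        rot = Rotation.from_rotvec(np.radians(20) * np.array([1.0, 0, 0])).as_matrix()
        for a in bent.atoms:
            if r.first_residue <= a.residue_number <= r.last_residue:
                a.position = rot @ (a.position - hinge) + hinge
        start = rmsd(bent.coords(), truth.coords())
        fitted, diag = flexible_fit(bent, truth_map15, resolution=15.0)
        final = rmsd(fitted.coords(), truth.coords())
        assert final <= 0.5 * start
        assert diag.cc_final >= diag.cc_initial

    def test_frozen_residues_do_not_move_at_all(self, manifest, truth_map15):
        truth = manifest.target_model
        bent = truth.transformed(RigidTransform(np.eye(3), np.array([2.0, 0, 0])))
        freeze = list(range(1, 21))
        fitted, _ = flexible_fit(bent, truth_map15, freeze=freeze, resolution=15.0)
        for a, b in zip(fitted.atoms, bent.atoms):
            if a.residue_number in set(freeze):
                assert np.allclose(a.position, b.position)

    def test_disconnected_network_error_lists_components(self):
        xyz = np.vstack([np.outer(np.arange(5), [3.8, 0, 0]),
                         np.outer(np.arange(5), [3.8, 0, 0]) + [100.0, 0, 0]])
        model = StructureModel([AtomRecord("A", i + 1, "GLY", "CA", p)
                                for i, p in enumerate(xyz)])
        from hybridem.structio import GridMap

        gm = GridMap(np.random.default_rng(0).random((64, 64, 64)), 2.0)
        with pytest.raises(FitError, match="disconnected"):
            flexible_fit(model, gm, resolution=15.0)

    def test_strain_guard_metric_reported(self, manifest, truth_map15):
        fitted, diag = flexible_fit(manifest.target_model, truth_map15,
                                    resolution=15.0)
        assert diag.strain_final >= 0.0
        assert diag.strain_initial == pytest.approx(0.0)

    def test_invalid_enm_params_rejected(self):
        with pytest.raises(FitError):
            ENMParams(cutoff=2.0)
        with pytest.raises(FitError):
            ENMParams(weights=(1.0, -0.5))
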