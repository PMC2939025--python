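"""Scaffold building, gap closure and fragment splicing."""

import numpy as np
import pytest

from hybridem.geometry import DomainRange, RigidTransform
from hybridem.scaffold import (AlignmentMapping, GraftAnchor,
                               InfeasibleClosureError, ScaffoldError,
                               SpliceMismatchError, SpliceSpec, build_scaffold,
                               delete_segment_and_close, graft_placed_insert,
                               splice_fragment)
from hybridem.structio import AtomRecord, StructureModel

from conftest import model_rmsd, rmsd


def _ca_chain(xyz, start=1, chain="A"):
    return StructureModel([
        AtomRecord(chain, start + i, "GLY", "CA", p, element="C")
        for i, p in enumerate(xyz)
    ])


class TestAlignmentMapping:
    def test_gapped_pair_parses_into_pairs_and_gaps(self):
        #   template: ABC---FG-
        #   target  : ABCDEFFGH   (DEF = target insert, trailing H too)
        m = AlignmentMapping.from_gapped_pair("ABC---FG-", "ABCDEFFGH")
        assert m.pairs == [(1, 1), (2, 2), (3, 3), (4, 7), (5, 8)]
        assert len(m.target_inserts) == 2
        first = m.target_inserts[0]
        assert (first.target_range.first_residue, first.target_range.last_residue) == (4, 6)
        assert (first.anchor_before, first.anchor_after) == (3, 7)

    def test_template_insert_recorded(self):
        m = AlignmentMapping.from_gapped_pair("ABCDEF", "AB--EF")
        assert len(m.template_inserts) == 1
        r = m.template_inserts[0].template_range
        assert (r.first_residue, r.last_residue) == (3, 4)

    def test_mapping_must_be_one_to_one(self):
        with pytest.raises(ScaffoldError):
            AlignmentMapping("A", "A", [(1, 1), (1, 2)])


class TestBuildScaffold:
    def test_identity_alignment_copies_backbone_with_target_numbering(self, manifest):
        tmpl = manifest.template_model
        n = len(tmpl.residue_numbers())
        mapping = AlignmentMapping("A", "A", [(i, i + 100) for i in range(1, n + 1)])
        res = build_scaffold(tmpl, mapping)
        assert len(res.model) == len(tmpl)
        assert res.model.residue_numbers() == [i + 100 for i in range(1, n + 1)]
        assert np.allclose(res.model.coords(), tmpl.coords())

    def test_synthetic_insert_bookkeeping(self, manifest):
        res = build_scaffold(manifest.template_model, manifest.mapping,
                             manifest.target_sequence)
        # one residue per aligned pair, Cα-only template
        assert len(res.model.residue_numbers()) == len(manifest.mapping.pairs)
        ins = manifest.insert_ranges["insA"]
        gap_lengths = {len(g.target_range) for g in res.pending_gaps}
        assert len(ins) in gap_lengths

    def test_template_insert_absent_from_scaffold(self, manifest):
        res = build_scaffold(manifest.template_model, manifest.mapping)
        tmpl_range = manifest.template_insert_ranges["tmplX"]
        scaffold_nums = set(res.model.residue_numbers())
        target_nums = {t for _, t in manifest.mapping.pairs}
        assert scaffold_nums == target_nums
        assert res.omitted_template_inserts[0].template_range == tmpl_range

    def test_missing_template_residue_is_listed(self, manifest):
        tmpl = manifest.template_model
        mapping = AlignmentMapping("A", "A", [(1, 1), (2, 2), (9999, 3)])
        with pytest.raises(ScaffoldError, match="9999"):
            build_scaffold(tmpl, mapping)


class TestDeleteAndClose:
    def test_zero_length_deletion_with_empty_bridge_is_a_noop(self, manifest):
        m = manifest.target_model
        out = delete_segment_and_close(m, DomainRange("A", 5000, 5000), ())
        assert len(out) == len(m)
        assert np.allclose(out.coords(), m.coords())

    def test_five_residue_bridge_spans_19_angstroms(self):
        xyz = np.vstack([[0, 0, 0], np.outer(np.arange(1, 8), [19 / 7, 0, 0]) ])
        # a chain 1..8 along x; delete residues 2..7 (anchors end up 19 Å apart)
        chain = _ca_chain(np.vstack([[0, 0, 0], np.outer(np.arange(1, 8), [19.0 / 7, 0, 0])]))
        bridge = [(n, "GLY") for n in range(2, 7)]
        out = delete_segment_and_close(chain, DomainRange("A", 2, 7), bridge)
        nums = out.residue_numbers()
        assert nums == [1, 2, 3, 4, 5, 6, 8]
        ca = out.ca_only().coords()
        gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(gaps <= 4.1 + 1e-6)

    def test_built_residues_flagged_by_zero_occupancy(self):
        chain = _ca_chain(np.outer(np.arange(8), [3.0, 0, 0]))
        out = delete_segment_and_close(chain, DomainRange("A", 4, 5),
                                       [(4, "ALA"), (5, "ALA")])
        built = [a for a in out.atoms if a.occupancy == 0.0]
        assert sorted(a.residue_number for a in built) == [4, 5]

    def test_infeasible_closure_raises_with_span(self):
        chain = _ca_chain(np.array([[0, 0, 0], [1, 0, 0], [51, 0, 0], [52, 0, 0]]))
        with pytest.raises(InfeasibleClosureError) as err:
            delete_segment_and_close(chain, DomainRange("A", 2, 3),
                                     [(n, "GLY") for n in range(2, 7)])
        assert err.value.span == pytest.approx(52.0)


class TestSpliceFragment:
    def test_identity_recovery_of_a_moved_cutout(self, manifest):
        scaffold = manifest.target_model
        region = DomainRange("A", 10, 50)
        cut = region.select(scaffold).copy()
        move = RigidTransform.from_rotvec([15, -40, 60], [8.0, -3.0, 5.0])
        fragment = cut.transformed(move)
        spec = SpliceSpec(shared_region=[(n, n) for n in range(10, 20)],
                          replace_range=region, insert_source=region)
        out, report = splice_fragment(scaffold, fragment, spec)
        assert rmsd(out.coords(), scaffold.coords()) < 1e-6
        assert report.shared_rmsd < 1e-6

    def test_synthetic_fragment_recovers_ground_truth(self, manifest):
        res = build_scaffold(manifest.template_model, manifest.mapping,
                             manifest.target_sequence)
        frag = manifest.fragments["insA"]
        out, report = splice_fragment(res.model, frag.model, frag.splice_spec)
        assert model_rmsd(out, manifest.target_model) < 1.0
        # junction spans are reported; with 0.25 Å template + 0.3 Å fragment
        # coordinate noise they sit near the 4.1 Å trans-peptide bound
        assert len(report.junction_spans) == 2
        assert all(s <= 4.1 + 3 * 0.55 for s in report.junction_spans)

    def test_atom_bookkeeping_is_exact(self, manifest):
        res = build_scaffold(manifest.template_model, manifest.mapping)
        frag = manifest.fragments["insA"]
        out, report = splice_fragment(res.model, frag.model, frag.splice_spec)
        assert len(out) == len(res.model) - report.n_removed + report.n_inserted

    def test_wrong_domain_splice_rejected(self, manifest):
        scaffold = manifest.target_model
        # a scrambled correspondence cannot be superposed rigidly: the
        # RMSD guard must refuse the splice
        scrambled = [(1, 60), (2, 20), (3, 75), (4, 40), (5, 90),
                     (6, 10), (7, 70), (8, 30), (9, 94), (10, 50)]
        spec = SpliceSpec(shared_region=scrambled,
                          replace_range=DomainRange("A", 41, 52),
                          insert_source=DomainRange("A", 41, 52))
        with pytest.raises(SpliceMismatchError):
            splice_fragment(scaffold, scaffold.copy(), spec)

    def test_untouched_atoms_do_not_move(self, manifest):
        res = build_scaffold(manifest.template_model, manifest.mapping)
        frag = manifest.fragments["insA"]
        spec = frag.splice_spec
        before = {a.residue_number: a.position.copy()
                  for a in res.model.atoms
                  if not (spec.replace_range.first_residue <= a.residue_number
                          <= spec.replace_range.last_residue)}
        out, _ = splice_fragment(res.model, frag.model, spec)
        for a in out.atoms:
            if a.residue_number in before:
                assert np.allclose(a.position, before[a.residue_number])


class TestGraft:
    def _setup(self, manifest):
        region = DomainRange("A", 26, 45)  # the insert block
        scaffold = StructureModel([
            a.copy() for a in manifest.target_model.atoms
            if not (region.first_residue <= a.residue_number <= region.last_residue)
        ])
        insert = region.select(manifest.target_model).copy()
        anchors = [GraftAnchor(25, 26, 0), GraftAnchor(46, 45, 0)]
        return scaffold, insert, anchors

    def test_native_placement_restores_ground_truth(self, manifest):
        scaffold, insert, anchors = self._setup(manifest)
        move = RigidTransform.from_rotvec([30, 10, -20], [10.0, 0.0, -6.0])
        displaced = insert.transformed(move)
        out, report = graft_placed_insert(scaffold, displaced, anchors,
                                          move.inverse())
        assert model_rmsd(out, manifest.target_model) < 1e-6
        assert report.clashes == []

    def test_faraway_placement_is_infeasible(self, manifest):
        scaffold, insert, anchors = self._setup(manifest)
        far = RigidTransform(np.eye(3), np.array([100.0, 0.0, 0.0]))
        with pytest.raises(InfeasibleClosureError) as err:
            graft_placed_insert(scaffold, insert, anchors, far)
        assert err.value.span > 90

    def test_placement_into_the_core_reports_clashes(self, manifest):
        scaffold, insert, anchors = self._setup(manifest)
        # push the insert into the first core helix
        target = scaffold.residue_ca("A", 10).position
        centroid = insert.coords().mean(axis=0)
        shove = RigidTransform(np.eye(3), target - centroid)
        anchors = [GraftAnchor(25, 26, 12), GraftAnchor(46, 45, 12)]
        out, report = graft_placed_insert(scaffold, insert, anchors, shove)
        assert len(report.clashes) > 0
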