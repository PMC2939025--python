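"""Homology-scaffold construction and fragment splicing.

A scaffold is built by copying template backbone atoms (N, CA, C, O, CB
when present) onto the target numbering for every aligned residue pair;
target-specific inserts (absent from the template) are left as pending
gaps, and template-specific inserts are omitted and closed with short
built loops. Fragment crystal structures carrying an insert plus a shared
anchor domain are then spliced in by Cα superposition of the shared
domain. Junction feasibility uses a generous trans-peptide Cα–Cα spacing
of 4.1 Å per bridged position; built loop residues are flagged with
occupancy 0.0 so measurements can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from hybridem.geometry import DomainRange, RigidTransform, superpose
from hybridem.structio import AtomRecord, StructureModel

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")
JUNCTION_CA_MAX = 4.1  # Å per bridged position
CLASH_CA_MIN = 3.0     # Å


class ScaffoldError(ValueError):
    pass


class InfeasibleClosureError(ScaffoldError):
    def __init__(self, msg: str, span: float):
        super().__init__(msg)
        self.span = span


class SpliceMismatchError(ScaffoldError):
    pass


# ---------------------------------------------------------------------------
# Alignment mapping
# ---------------------------------------------------------------------------

@dataclass
class InsertGap:
    """A target-side insert: residues with no template equivalent."""

    target_range: DomainRange
    anchor_before: int | None   # target residue number flanking the gap
    anchor_after: int | None


@dataclass
class TemplateInsert:
    """A template-side insert: template residues to omit, with the target
    loop range that bridges the resulting gap."""

    template_range: DomainRange
    bridge_range: DomainRange | None = None


@dataclass
class AlignmentMapping:
    """Template↔target residue correspondence for one chain pair."""

    template_chain: str
    target_chain: str
    pairs: list[tuple[int, int]]  # (template residue, target residue)
    target_inserts: list[InsertGap] = field(default_factory=list)
    template_inserts: list[TemplateInsert] = field(default_factory=list)

    def __post_init__(self) -> None:
        tmpl = [t for t, _ in self.pairs]
        targ = [t for _, t in self.pairs]
        if len(set(tmpl)) != len(tmpl) or len(set(targ)) != len(targ):
            raise ScaffoldError("alignment mapping is not one-to-one")

    @classmethod
    def from_gapped_pair(cls, template_seq: str, target_seq: str,
                         template_chain: str = "A", target_chain: str = "A",
                         template_start: int = 1, target_start: int = 1,
                         ) -> "AlignmentMapping":
        """Build a mapping from two gapped rows of a pairwise alignment."""
        if len(template_seq) != len(target_seq):
            raise ScaffoldError("gapped rows differ in length")
        pairs: list[tuple[int, int]] = []
        target_inserts: list[InsertGap] = []
        template_inserts: list[TemplateInsert] = []
        it, ig = template_start - 1, target_start - 1
        run_kind, run_start = None, 0
        runs: list[tuple[str, int, int]] = []  # (kind, first, last) in residue numbers

        for ct, cg in zip(template_seq, target_seq):
            gap_t, gap_g = ct in "-.~", cg in "-.~"
            if gap_t and gap_g:
                continue
            if not gap_t:
                it += 1
            if not gap_g:
                ig += 1
            if not gap_t and not gap_g:
                pairs.append((it, ig))
                run_kind = None
            elif gap_t:  # target insert
                if run_kind != "target":
                    runs.append(("target", ig, ig))
                    run_kind = "target"
                else:
                    runs[-1] = ("target", runs[-1][1], ig)
            else:        # template insert
                if run_kind != "template":
                    runs.append(("template", it, it))
                    run_kind = "template"
                else:
                    runs[-1] = ("template", runs[-1][1], it)

        targ_by_first = {t: i for i, (_, t) in enumerate(pairs)}
        for kind, first, last in runs:
            if kind == "target":
                before = max((t for _, t in pairs if t < first), default=None)
                after = min((t for _, t in pairs if t > last), default=None)
                target_inserts.append(InsertGap(
                    DomainRange(target_chain, first, last), before, after))
            else:
                template_inserts.append(TemplateInsert(
                    DomainRange(template_chain, first, last)))
        del targ_by_first
        return cls(template_chain, target_chain, pairs, target_inserts, template_inserts)


# ---------------------------------------------------------------------------
# Scaffold building
# ---------------------------------------------------------------------------

class ScaffoldResult(NamedTuple):
    model: StructureModel
    pending_gaps: list[InsertGap]
    omitted_template_inserts: list[TemplateInsert]


def build_scaffold(template: StructureModel, mapping: AlignmentMapping,
                   target_sequence: dict[int, str] | None = None) -> ScaffoldResult:
    """Copy template backbone onto target numbering for aligned residues.

    ``target_sequence`` optionally maps target residue numbers to 3-letter
    residue names; otherwise template names are kept. Aligned residues
    missing from the template coordinates raise an error listing them.
    """
    by_res: dict[int, list[AtomRecord]] = {}
    for a in template.select(chain_id=mapping.template_chain):
        by_res.setdefault(a.residue_number, []).append(a)
    missing = [t for t, _ in mapping.pairs if t not in by_res]
    if missing:
        raise ScaffoldError(
            f"aligned template residues missing from coordinates: {missing}")
    atoms: list[AtomRecord] = []
    for tmpl_res, targ_res in sorted(mapping.pairs, key=lambda p: p[1]):
        for a in by_res[tmpl_res]:
            if a.atom_name not in BACKBONE_ATOMS:
                continue
            c = a.copy()
            c.chain_id = mapping.target_chain
            c.residue_number = targ_res
            if target_sequence and targ_res in target_sequence:
                c.residue_name = target_sequence[targ_res]
            atoms.append(c)
    return ScaffoldResult(StructureModel(atoms), list(mapping.target_inserts),
                          list(mapping.template_inserts))


# ---------------------------------------------------------------------------
# Gap closure
# ---------------------------------------------------------------------------

def _relax_spacing(points: np.ndarray, lo: float = 2.9, hi: float = 4.1,
                   target: float = 3.5, n_iter: int = 200) -> np.ndarray:
    """Nudge interior points so consecutive spacings land in [lo, hi].

    Endpoints stay fixed; a deterministic perpendicular bulge is added
    first so over-short chords can expand.
    """
    pts = points.copy()
    if len(pts) < 3:
        return pts
    chord = pts[-1] - pts[0]
    perp = np.cross(chord, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(chord, [0.0, 1.0, 0.0])
    perp = perp / max(np.linalg.norm(perp), 1e-12)
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if arc < lo * (len(pts) - 1):
        # genuinely compressed trace: bow it out just far enough that the
        # spacing iteration below can reach the plausible band
        need = target * (len(pts) - 1)
        s = np.sin(np.linspace(0, np.pi, len(pts)))
        pts = pts + np.outer(s, perp) * 0.5 * np.sqrt(max(need**2 - arc**2, 0.0))
    for _ in range(n_iter):
        deltas = np.diff(pts, axis=0)
        dists = np.linalg.norm(deltas, axis=1)
        if np.all((dists >= lo) & (dists <= hi)):
            break
        corr = np.zeros_like(pts)
        for i, d in enumerate(dists):
            if d < 1e-9:
                continue
            want = np.clip(d, lo + 0.1, hi - 0.1)
            adj = 0.5 * (d - want) / d * deltas[i]
            corr[i] += adj
            corr[i + 1] -= adj
        corr[0] = corr[-1] = 0.0
        pts = pts + corr
    return pts


def _build_bridge_trace(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
    """n Cα positions evenly interpolated between anchors, then relaxed."""
    span = float(np.linalg.norm(end - start))
    if span > JUNCTION_CA_MAX * (n + 1):
        raise InfeasibleClosureError(
            f"anchors {span:.1f} Å apart cannot be bridged by {n} residues "
            f"(limit {JUNCTION_CA_MAX * (n + 1):.1f} Å)", span)
    ts = np.arange(1, n + 1) / (n + 1)
    pts = start + np.outer(ts, end - start)
    full = np.vstack([start, pts, end])
    relaxed = _relax_spacing(full)
    return relaxed[1:-1]


def delete_segment_and_close(model: StructureModel, segment: DomainRange,
                             bridge: Sequence[tuple[int, str]] = (),
                             ) -> StructureModel:
    """Remove a residue segment and close the gap with a built Cα loop.

    ``bridge`` lists (residue number, 3-letter name) pairs for the loop to
    build between the residues flanking the deleted segment; built atoms
    carry occupancy 0.0. A zero-length deletion with an empty bridge is a
    no-op. Anchors farther apart than 4.1 Å × (bridge length + 1) raise
    :class:`InfeasibleClosureError`.
    """
    removed_ids = {id(a) for a in segment.select(model).atoms}
    remaining = [a for a in model.atoms if id(a) not in removed_ids]
    if not removed_ids and not bridge:
        return StructureModel(a.copy() for a in model.atoms)
    kept = StructureModel(remaining)
    nums = kept.residue_numbers(segment.chain_id)
    before = max((r for r in nums if r < segment.first_residue), default=None)
    after = min((r for r in nums if r > segment.last_residue), default=None)
    if before is None or after is None:
        raise ScaffoldError(
            f"segment {segment.first_residue}–{segment.last_residue} has no "
            "flanking anchor residues on both sides")
    start = kept.residue_ca(segment.chain_id, before).position
    end = kept.residue_ca(segment.chain_id, after).position
    trace = _build_bridge_trace(start, end, len(bridge))
    bridge_atoms = [
        AtomRecord(chain_id=segment.chain_id, residue_number=num,
                   residue_name=name, atom_name="CA", element="C",
                   position=pos, occupancy=0.0)
        for (num, name), pos in zip(bridge, trace)
    ]
    # insert bridge atoms in chain order, right after the 'before' residue
    out: list[AtomRecord] = []
    inserted = False
    for i, a in enumerate(remaining):
        out.append(a.copy())
        nxt = remaining[i + 1] if i + 1 < len(remaining) else None
        last_of_before = (a.chain_id == segment.chain_id
                          and a.residue_number == before
                          and (nxt is None or nxt.chain_id != segment.chain_id
                               or nxt.residue_number != before))
        if not inserted and last_of_before:
            out.extend(bridge_atoms)
            inserted = True
    return StructureModel(out)


# ---------------------------------------------------------------------------
# Fragment splicing
# ---------------------------------------------------------------------------

@dataclass
class SpliceSpec:
    """How to splice a fragment into a scaffold.

    ``shared_region`` lists (scaffold residue, fragment residue) Cα
    correspondences used for the superposition; ``replace_range`` is
    deleted from the scaffold; ``insert_source`` is copied (transformed)
    from the fragment.
    """

    shared_region: list[tuple[int, int]]
    replace_range: DomainRange
    insert_source: DomainRange
    scaffold_chain: str = "A"
    fragment_chain: str = "A"

    def __post_init__(self) -> None:
        if len(self.shared_region) < 3:
            raise ScaffoldError("shared region needs ≥ 3 correspondences")


class SpliceReport(NamedTuple):
    shared_rmsd: float
    transform: RigidTransform
    junction_spans: list[float]
    n_removed: int
    n_inserted: int


def _junction_spans(model: StructureModel, chain: str,
                    first: int, last: int) -> list[float]:
    """Cα spacing across the two junctions of an inserted residue block."""
    spans = []
    nums = model.residue_numbers(chain)
    before = max((r for r in nums if r < first), default=None)
    after = min((r for r in nums if r > last), default=None)
    for a, b in ((before, first), (last, after)):
        if a is None or b is None:
            continue
        try:
            ca1 = model.residue_ca(chain, a).position
            ca2 = model.residue_ca(chain, b).position
        except KeyError:
            continue
        spans.append(float(np.linalg.norm(ca1 - ca2)))
    return spans


def _insert_block(scaffold_atoms: list[AtomRecord], new_atoms: list[AtomRecord],
                  chain: str, first: int) -> list[AtomRecord]:
    """Place a residue block at its numeric position within the chain."""
    out: list[AtomRecord] = []
    placed = False
    for a in scaffold_atoms:
        if (not placed and a.chain_id == chain and a.residue_number > first):
            out.extend(new_atoms)
            placed = True
        out.append(a)
    if not placed:
        out.extend(new_atoms)
    return out


def splice_fragment(scaffold: StructureModel, fragment: StructureModel,
                    spec: SpliceSpec, max_shared_rmsd: float = 5.0,
                    ) -> tuple[StructureModel, SpliceReport]:
    """Splice a fragment into the scaffold by shared-domain superposition.

    The fragment is rigidly superposed onto the scaffold via the shared
    region's Cα atoms; a shared-region RMSD above ``max_shared_rmsd``
    (default 5 Å) aborts with :class:`SpliceMismatchError` to guard
    against wrong-domain splices. Atom bookkeeping is exact:
    len(result) = len(scaffold) − removed + inserted.
    """
    try:
        scaf_ca = np.array([scaffold.residue_ca(spec.scaffold_chain, r).position
                            for r, _ in spec.shared_region])
        frag_ca = np.array([fragment.residue_ca(spec.fragment_chain, r).position
                            for _, r in spec.shared_region])
    except KeyError as exc:
        raise ScaffoldError(f"shared-region residue missing: {exc}") from None
    sup = superpose(frag_ca, scaf_ca)
    if sup.rmsd > max_shared_rmsd:
        raise SpliceMismatchError(
            f"shared-region RMSD {sup.rmsd:.2f} Å exceeds {max_shared_rmsd} Å — "
            "likely a wrong-domain splice")
    removed = set(id(a) for a in spec.replace_range.select(scaffold).atoms)
    kept = [a.copy() for a in scaffold.atoms if id(a) not in removed]
    source = spec.insert_source.select(fragment)
    placed = []
    for a in source.atoms:
        c = a.copy()
        c.chain_id = spec.scaffold_chain
        c.position = sup.transform.apply(c.position[None, :])[0]
        placed.append(c)
    atoms = _insert_block(kept, placed, spec.scaffold_chain,
                          spec.insert_source.first_residue)
    model = StructureModel(atoms)
    spans = _junction_spans(model, spec.scaffold_chain,
                            spec.insert_source.first_residue,
                            spec.insert_source.last_residue)
    report = SpliceReport(sup.rmsd, sup.transform, spans, len(removed), len(placed))
    return model, report


# ---------------------------------------------------------------------------
# Grafting a placed insert
# ---------------------------------------------------------------------------

@dataclass
class GraftAnchor:
    """One junction: scaffold anchor residue ↔ insert terminal residue."""

    scaffold_residue: int
    insert_residue: int
    missing_residues: int = 0


class GraftReport(NamedTuple):
    junction_spans: list[float]
    clashes: list[tuple[int, int, float]]  # (scaffold res, insert res, Å)


def graft_placed_insert(scaffold: StructureModel, insert: StructureModel,
                        anchors: Sequence[GraftAnchor], placement: RigidTransform,
                        scaffold_chain: str = "A", insert_chain: str = "A",
                        ) -> tuple[StructureModel, GraftReport]:
    """Add an insert under an externally determined rigid placement.

    Junction feasibility follows the splice rule (4.1 Å per bridged
    position); an infeasible junction raises
    :class:`InfeasibleClosureError` carrying the measured span. Cα pairs
    closer than 3.0 Å between the placed insert and the scaffold are
    reported as clashes (anchor junction pairs excluded).
    """
    placed = insert.transformed(placement)
    spans = []
    for anc in anchors:
        try:
            s_ca = scaffold.residue_ca(scaffold_chain, anc.scaffold_residue).position
            i_ca = placed.residue_ca(insert_chain, anc.insert_residue).position
        except KeyError as exc:
            raise ScaffoldError(f"graft anchor missing: {exc}") from None
        span = float(np.linalg.norm(s_ca - i_ca))
        spans.append(span)
        limit = JUNCTION_CA_MAX * (anc.missing_residues + 1)
        if span > limit:
            raise InfeasibleClosureError(
                f"junction span {span:.1f} Å exceeds {limit:.1f} Å "
                f"({anc.missing_residues} missing residues)", span)
    scaf_ca = scaffold.ca_only(scaffold_chain)
    ins_ca = placed.ca_only(insert_chain)
    anchor_res = {a.scaffold_residue for a in anchors}
    term_res = {a.insert_residue for a in anchors}
    clashes = []
    if len(scaf_ca) and len(ins_ca):
        d = np.linalg.norm(scaf_ca.coords()[:, None, :] - ins_ca.coords()[None, :, :],
                           axis=2)
        for i, j in zip(*np.where(d < CLASH_CA_MIN)):
            rs = scaf_ca.atoms[i].residue_number
            ri = ins_ca.atoms[j].residue_number
            if rs in anchor_res or ri in term_res:
                continue
            clashes.append((rs, ri, float(d[i, j])))
    new_atoms = []
    for a in placed.atoms:
        c = a.copy()
        c.chain_id = scaffold_chain
        new_atoms.append(c)
    first = min(a.residue_number for a in placed.atoms)
    atoms = _insert_block([a.copy() for a in scaffold.atoms], new_atoms,
                          scaffold_chain, first)
    return StructureModel(atoms), GraftReport(spans, clashes)
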