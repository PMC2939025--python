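"""Seeded generators for every input the pipeline needs, with ground truth.

The toy system is a "mini-polymerase": a multi-helix core shared by a
template and a target, where the target carries extra hairpin inserts
(absent from the template) and the template carries its own inserts
(absent from the target, bridged by a short target loop). Fragment
structures cut from the ground truth around each target insert — anchor
helix plus insert, coordinate-perturbed and rigidly displaced — stand in
for independently solved crystal fragments. Everything is Cα-trace
geometry built from ideal α-helices (rise 1.5 Å, 100° twist, 2.3 Å
radius) and equal-spacing hairpin loops: simple, clash-checkable and
projection-friendly, with no attempt at a realistic fold.

All generators are pure functions of spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from hybridem.emmap import simulate_map
from hybridem.geometry import DomainRange, RigidTransform
from hybridem.scaffold import (AlignmentMapping, InsertGap, SpliceSpec,
                               TemplateInsert, _build_bridge_trace)
from hybridem.spreconstruct import OrientationParams, ParticleImage, project
from hybridem.structio import AtomRecord, GridMap, MultipleAlignment, StructureModel

AA3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"]
AA1 = "ARNDCQEGHILKMFPSTWYV"

HELIX_RISE = 1.5     # Å per residue along the axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3   # Å


class GenerationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Geometric building blocks
# ---------------------------------------------------------------------------

def ideal_helix(n: int, start=(0.0, 0.0, 0.0), axis=(1.0, 0.0, 0.0),
                phase: float = 0.0) -> np.ndarray:
    """n Cα positions of an ideal α-helix along an arbitrary axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    i = np.arange(n)
    ang = np.radians(phase + HELIX_TWIST * i)
    pts = (np.asarray(start, dtype=float)
           + np.outer(HELIX_RISE * i, axis)
           + HELIX_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)))
    return pts


def _equal_arc_points(path: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc length along a polyline (endpoints excluded)."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n + 2)[1:-1]
    out = np.empty((n, 3))
    for k, t in enumerate(targets):
        i = np.searchsorted(cum, t, side="right") - 1
        i = min(i, len(seg) - 1)
        frac = (t - cum[i]) / max(seg[i], 1e-12)
        out[k] = path[i] + frac * (path[i + 1] - path[i])
    return out


def hairpin_trace(anchor_start: np.ndarray, anchor_end: np.ndarray, n: int,
                  direction=(0.0, 0.0, 1.0), spacing: float = 3.6,
                  width: float = 10.0) -> np.ndarray:
    """n Cα positions forming an out-and-back hairpin between two anchors.

    The hairpin extends along ``direction`` far enough that consecutive
    Cα spacing lands near ``spacing`` Å.
    """
    a, b = np.asarray(anchor_start, float), np.asarray(anchor_end, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    apex_gap = max(width, float(np.linalg.norm(a - b)))
    reach = max(spacing, (spacing * (n + 1) - apex_gap) / 2.0)
    mid = (a + b) / 2.0
    side = np.cross([0.0, 1.0, 0.0], d)
    if np.linalg.norm(side) < 1e-6:
        side = np.cross([1.0, 0.0, 0.0], d)
    side /= np.linalg.norm(side)
    apex1 = mid + d * reach + side * apex_gap / 2.0
    apex2 = mid + d * reach - side * apex_gap / 2.0
    # standoff waypoints lift the legs clear of the chain flanking the anchors
    lift = min(3.0, reach / 2.0)
    path = np.array([a, a + d * lift + side * apex_gap / 2.0, apex1,
                     apex2, b + d * lift - side * apex_gap / 2.0, b])
    pts = _equal_arc_points(path, n)
    # corners of the polyline compress Euclidean spacing; relax it back
    # into the plausible Cα band
    from hybridem.scaffold import _relax_spacing

    relaxed = _relax_spacing(np.vstack([a, pts, b]))
    return relaxed[1:-1]


def _loop_points(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Short connector loop: even interpolation between two anchors."""
    ts = np.arange(1, n + 1) / (n + 1)
    return a + np.outer(ts, b - a)


def _ca_model(xyz: np.ndarray, residue_numbers: Sequence[int],
              residue_names: Sequence[str], chain: str = "A") -> StructureModel:
    atoms = [AtomRecord(chain_id=chain, residue_number=num, residue_name=name,
                        atom_name="CA", element="C", position=pos)
             for pos, num, name in zip(xyz, residue_numbers, residue_names)]
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Toy system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertSpec:
    """One insert: length and the core ordinal it attaches after."""

    name: str
    length: int
    attach_after: int            # ordinal among core residues (1-based)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    bridge_length: int = 2       # target bridge residues (template inserts only)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenerationError("insert length must be positive")


@dataclass(frozen=True)
class ToySystemSpec:
    seed: int = 0
    # tapered helix lengths + a staircase z-offset make the fold strongly
    # asymmetric and chiral, so projection directions are distinguishable
    # (orientation assignment is ill-posed for a quasi-symmetric particle)
    helix_lengths: tuple[int, ...] = (24, 18, 14, 10)
    loop_len: int = 3
    domain_spacing: float = 10.0
    domain_z_step: float = 6.0
    # skew along x keeps successive connector spans near 12 Å, so 3-residue
    # loops bridge them at plausible Cα spacing
    domain_x_step: float = 3.0
    # inserts attach in the connector loops between core domains, as
    # lineage-specific inserts do between shared regions
    # the insert leaves the bundle tilted away from the helix rows so its
    # hairpin legs clear the neighbouring domains
    target_inserts: tuple[InsertSpec, ...] = (
        InsertSpec("insA", 20, 25, (0.0, -0.45, 0.89)),
    )
    template_inserts: tuple[InsertSpec, ...] = (
        InsertSpec("tmplX", 12, 64, (0.0, 0.0, -1.0)),
    )
    fragment_anchor_halfwidth: int = 9
    fragment_perturbation: float = 0.3   # Å Gaussian coordinate noise
    template_core_noise: float = 0.25    # Å template/target core divergence
    map_resolution: float = 10.0         # Å
    voxel_size: float = 2.0              # Å
    box_size: int = 32
    n_particles: int = 400
    snr: float = 1.0

    @property
    def n_core_domains(self) -> int:
        return len(self.helix_lengths)

    @property
    def n_core(self) -> int:
        return (sum(self.helix_lengths)
                + (self.n_core_domains - 1) * self.loop_len)


@dataclass
class Fragment:
    """A displaced, noise-perturbed cutout of the ground truth."""

    name: str
    model: StructureModel            # coordinates as "deposited"
    applied: RigidTransform          # motion applied when cutting it out
    true_placement: RigidTransform   # inverse: maps fragment → truth frame
    splice_spec: SpliceSpec
    insert_range: DomainRange        # target numbering


@dataclass
class SystemManifest:
    spec: ToySystemSpec
    seed: int
    target_model: StructureModel     # ground truth, chain A
    template_model: StructureModel   # chain A, template numbering
    mapping: AlignmentMapping
    target_sequence: dict[int, str]
    fragments: dict[str, Fragment]
    insert_ranges: dict[str, DomainRange]
    template_insert_ranges: dict[str, DomainRange]
    bridges: dict[str, list[tuple[int, str]]]  # per template insert
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)


def _core_trace(spec: ToySystemSpec) -> np.ndarray:
    """Continuous Cα trace of the core: stacked antiparallel helices."""
    pts: list[np.ndarray] = []
    prev_end = None
    for d, h_len in enumerate(spec.helix_lengths):
        sign = 1 if d % 2 == 0 else -1
        x0 = (0.0 if sign > 0 else (h_len - 1) * HELIX_RISE) + d * spec.domain_x_step
        start = np.array([x0, d * spec.domain_spacing, d * spec.domain_z_step])
        helix = ideal_helix(h_len, start, (sign, 0.0, 0.0),
                            phase=37.0 * d)
        if prev_end is not None and spec.loop_len > 0:
            # relaxed trace keeps connector spacing in the plausible band
            # even where helix-surface endpoints curl close together
            pts.append(_build_bridge_trace(prev_end, helix[0], spec.loop_len))
        pts.append(helix)
        prev_end = helix[-1]
    return np.vstack(pts)


def make_toy_system(spec: ToySystemSpec) -> SystemManifest:
    """Generate the full synthetic system with recorded ground truth."""
    rng = np.random.default_rng(spec.seed)
    core = _core_trace(spec)
    n_core = len(core)
    for ins in list(spec.target_inserts) + list(spec.template_inserts):
        if not 1 <= ins.attach_after < n_core:
            raise GenerationError(
                f"insert {ins.name} attaches after core residue {ins.attach_after}, "
                f"outside 1–{n_core - 1}")

    # --- target ground truth: core + target inserts (+ bridge loops at
    #     template-insert sites), numbered 1..N in chain order
    events = sorted(
        [("target", ins) for ins in spec.target_inserts]
        + [("template", ins) for ins in spec.template_inserts],
        key=lambda e: e[1].attach_after)
    names = set(i.name for _, i in events)
    if len(names) != len(events):
        raise GenerationError("insert names must be unique")

    target_xyz: list[np.ndarray] = []
    target_kind: list[tuple[str, str]] = []  # (kind, insert name) per residue
    tmpl_extra: dict[int, InsertSpec] = {}   # template inserts keyed by core ordinal
    cursor = 0
    for kind, ins in events:
        target_xyz.extend(core[cursor:ins.attach_after])
        target_kind.extend([("core", "")] * (ins.attach_after - cursor))
        cursor = ins.attach_after
        a, b = core[cursor - 1], core[cursor]
        if kind == "target":
            pts = hairpin_trace(a, b, ins.length, ins.direction)
            target_xyz.extend(pts)
            target_kind.extend([("insert", ins.name)] * ins.length)
        else:
            tmpl_extra[cursor] = ins
            if ins.bridge_length > 0:
                # ground-truth bridge = the same relaxed trace the gap-closure
                # operation builds, so closure is exactly recoverable
                pts = _build_bridge_trace(a, b, ins.bridge_length)
                target_xyz.extend(pts)
                target_kind.extend([("bridge", ins.name)] * ins.bridge_length)
    target_xyz.extend(core[cursor:])
    target_kind.extend([("core", "")] * (n_core - cursor))
    target_xyz = np.array(target_xyz)

    # attachment-clash guard: any insert/bridge atom against the rest of
    # the chain (sequence separation > 2); the fixed core geometry is
    # known-good by construction
    from scipy.spatial.distance import squareform

    dm = squareform(pdist(target_xyz))
    n_t = len(target_xyz)
    ii, jj = np.triu_indices(n_t, k=3)
    insertish = np.array([k != "core" for k, _ in target_kind])
    sel = insertish[ii] | insertish[jj]
    if sel.any():
        dmin = dm[ii[sel], jj[sel]].min()
        if dmin < 2.5:
            raise GenerationError(
                f"insert attachments clash: minimum Cα–Cα distance {dmin:.2f} Å")

    n_target = len(target_xyz)
    target_names = [AA3[i] for i in rng.integers(0, 20, n_target)]
    target_model = _ca_model(target_xyz, range(1, n_target + 1), target_names)
    target_sequence = {i + 1: target_names[i] for i in range(n_target)}

    # --- template: core (with small divergence) + template inserts,
    #     numbered 1..M in its own chain order
    tmpl_core = core + spec.template_core_noise * rng.standard_normal(core.shape)
    tmpl_xyz: list[np.ndarray] = []
    tmpl_is_insert: list[str] = []
    for i in range(n_core):
        tmpl_xyz.append(tmpl_core[i])
        tmpl_is_insert.append("")
        ins = tmpl_extra.get(i + 1)
        if ins is not None:
            pts = hairpin_trace(tmpl_core[i], tmpl_core[i + 1], ins.length,
                                ins.direction)
            tmpl_xyz.extend(pts)
            tmpl_is_insert.extend([ins.name] * ins.length)
    tmpl_xyz = np.array(tmpl_xyz)
    n_tmpl = len(tmpl_xyz)

    # --- alignment mapping between the two numbering schemes
    core_target_num: list[int] = []   # target residue number of each core ordinal
    insert_ranges: dict[str, DomainRange] = {}
    bridges: dict[str, list[tuple[int, str]]] = {}
    run_first: dict[str, int] = {}
    for idx, (kind, name) in enumerate(target_kind):
        num = idx + 1
        if kind == "core":
            core_target_num.append(num)
        else:
            run_first.setdefault(name, num)
            if kind == "insert":
                insert_ranges[name] = DomainRange("A", run_first[name], num)
            else:
                bridges.setdefault(name, []).append((num, target_sequence[num]))
    core_tmpl_num = [i + 1 for i, nm in enumerate(tmpl_is_insert) if nm == ""]
    template_insert_ranges = {}
    for nm in {n for n in tmpl_is_insert if n}:
        idxs = [i + 1 for i, x in enumerate(tmpl_is_insert) if x == nm]
        template_insert_ranges[nm] = DomainRange("A", min(idxs), max(idxs))
    pairs = list(zip(core_tmpl_num, core_target_num))

    tmpl_names = []
    k = 0
    for i, nm in enumerate(tmpl_is_insert):
        if nm == "":
            tmpl_names.append(target_sequence[core_target_num[k]])
            k += 1
        else:
            tmpl_names.append(AA3[int(rng.integers(0, 20))])
    template_model = _ca_model(tmpl_xyz, range(1, n_tmpl + 1), tmpl_names)

    target_gaps = [
        InsertGap(rng_, _neighbor(core_target_num, rng_.first_residue, -1),
                  _neighbor(core_target_num, rng_.last_residue, +1))
        for rng_ in insert_ranges.values()
    ] + [
        InsertGap(DomainRange("A", nums[0][0], nums[-1][0]),
                  _neighbor(core_target_num, nums[0][0], -1),
                  _neighbor(core_target_num, nums[-1][0], +1))
        for nums in bridges.values()
    ]
    mapping = AlignmentMapping(
        "A", "A", pairs,
        target_inserts=target_gaps,
        template_inserts=[TemplateInsert(r) for r in template_insert_ranges.values()],
    )

    # --- fragments: anchor region + insert, perturbed and displaced
    fragments: dict[str, Fragment] = {}
    for ins in spec.target_inserts:
        r = insert_ranges[ins.name]
        hw = spec.fragment_anchor_halfwidth
        lo = max(1, r.first_residue - hw)
        hi = min(n_target, r.last_residue + hw)
        cut = DomainRange("A", lo, hi).select(target_model)
        noisy = cut.copy()
        noisy.set_coords(cut.coords()
                         + spec.fragment_perturbation
                         * rng.standard_normal((len(cut), 3)))
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-15.0, 15.0, 3)
        applied = RigidTransform(rot, trans)
        frag_model = noisy.transformed(applied)
        anchor_res = ([n for n in range(lo, r.first_residue)]
                      + [n for n in range(r.last_residue + 1, hi + 1)])
        splice = SpliceSpec(
            shared_region=[(n, n) for n in anchor_res],
            replace_range=DomainRange("A", lo, hi),
            insert_source=DomainRange("A", lo, hi),
        )
        fragments[ins.name] = Fragment(ins.name, frag_model, applied,
                                       applied.inverse(), splice, r)

    return SystemManifest(spec, spec.seed, target_model, template_model, mapping,
                          target_sequence, fragments, insert_ranges,
                          template_insert_ranges, bridges, pairs)


def _neighbor(core_nums: list[int], num: int, direction: int) -> int | None:
    if direction < 0:
        cand = [n for n in core_nums if n < num]
        return max(cand) if cand else None
    cand = [n for n in core_nums if n > num]
    return min(cand) if cand else None


def make_map(manifest: SystemManifest, resolution: float | None = None,
             voxel_size: float | None = None, box_size: int | None = None,
             noise_sigma_fraction: float = 0.0, seed: int = 0) -> GridMap:
    """Simulate the 'experimental' map from the ground-truth model.

    Optional additive Gaussian noise with σ = fraction × map max.
    """
    spec = manifest.spec
    gm = simulate_map(manifest.target_model,
                      resolution or spec.map_resolution,
                      voxel_size or spec.voxel_size,
                      box_size or spec.box_size)
    if noise_sigma_fraction > 0:
        rng = np.random.default_rng(seed)
        gm.values = gm.values + (noise_sigma_fraction * gm.values.max()
                                 * rng.standard_normal(gm.values.shape))
    return gm


def make_two_lobe_fragment(helix_len: int = 12, separation: float = 7.0,
                           resolution: float = 10.0, voxel_size: float = 2.0,
                           box_size: int = 32):
    """Near-C2-symmetric two-helix fragment plus anchors and density.

    Emulates the orientation-disambiguation problem of a pseudo-symmetric
    insert: two antiparallel helices fit their own density equally well in
    two orientations related by a 180° flip, but only one orientation can
    bridge the sequence gap to the scaffold anchors. Returns
    (fragment, scaffold, linkers, density); the fragment is in its true
    placement (identity transform).
    """
    from hybridem.densityfit import LinkerSpec

    h1 = ideal_helix(helix_len, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    h2 = ideal_helix(helix_len, ((helix_len - 1) * HELIX_RISE, separation, 0.0),
                     (-1.0, 0.0, 0.0))
    xyz = np.vstack([h1, h2])
    n = 2 * helix_len
    fragment = _ca_model(xyz, range(1, n + 1), ["ALA"] * n)
    density = simulate_map(fragment, resolution, voxel_size, box_size)
    anchors = np.array([xyz[0] + [-4.0, 0.0, 0.0], xyz[-1] + [-4.0, 0.0, 0.0]])
    scaffold = _ca_model(anchors, [1, 2], ["GLY", "GLY"])
    linkers = [LinkerSpec(1, 1, 1), LinkerSpec(2, n, 1)]
    return fragment, scaffold, linkers, density


# ---------------------------------------------------------------------------
# Particle stacks
# ---------------------------------------------------------------------------

def make_particles(volume: GridMap, n: int, snr: float, seed: int = 0,
                   ) -> tuple[list[ParticleImage], list[OrientationParams]]:
    """n noisy projections at uniformly random orientations.

    Noise is additive Gaussian with variance = signal variance / SNR,
    measured per image over all pixels. The truth table (one orientation
    per image) is returned and also attached to each image.
    """
    if n < 1:
        raise GenerationError("need at least one particle")
    if not snr > 0:
        raise GenerationError("snr must be positive")
    rng = np.random.default_rng(seed)
    truths: list[OrientationParams] = []
    images: list[ParticleImage] = []
    for _ in range(n):
        phi, theta, psi = Rotation.random(rng=rng).as_euler("ZYZ", degrees=True)
        op = OrientationParams(float(phi) % 360.0, float(theta), float(psi) % 360.0)
        clean = project(volume, op)
        sig_var = float(clean.pixels.var())
        noise = np.sqrt(sig_var / snr) * rng.standard_normal(clean.pixels.shape)
        img = ParticleImage(clean.pixels + noise, clean.pixel_size, truth=op)
        truths.append(op)
        images.append(img)
    return images, truths


# ---------------------------------------------------------------------------
# Synthetic alignments
# ---------------------------------------------------------------------------

@dataclass
class MsaManifest:
    consensus: str
    conservation: np.ndarray
    realized_fractions: np.ndarray
    insert_blocks: list[tuple[int, int, float]]  # (after ref position, length, row fraction)
    reference_id: str


def make_msa(n_rows: int, conservation: Sequence[float],
             insert_blocks: Sequence[tuple[int, int, float]] = (),
             seed: int = 0, reference_id: str = "ref",
             ) -> tuple[MultipleAlignment, MsaManifest]:
    """Alignment with specified per-column conservation and insert blocks.

    Column c carries the consensus residue with probability
    ``conservation[c]``, otherwise a uniformly random different residue.
    Each insert block (after_position, length, row_fraction) opens a gap
    run in the reference row after that reference position; the stated
    fraction of the other rows carry an insertion there, at least one of
    them of the full length.
    """
    cons = np.asarray(conservation, dtype=float)
    if np.any((cons < 0) | (cons > 1)):
        raise GenerationError("conservation values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cols = len(cons)
    consensus = "".join(AA1[i] for i in rng.integers(0, 20, n_cols))
    base = np.empty((n_rows, n_cols), dtype="U1")
    for c in range(n_cols):
        keep = rng.random(n_rows) < cons[c]
        others = [a for a in AA1 if a != consensus[c]]
        for r in range(n_rows):
            base[r, c] = consensus[c] if keep[r] else others[int(rng.integers(0, 19))]
    base[0, :] = list(consensus)  # reference row matches consensus exactly

    columns: list[list[str]] = [list(base[:, c]) for c in range(n_cols)]
    # splice insert blocks (in descending position so indices stay valid)
    for after, length, frac in sorted(insert_blocks, key=lambda b: -b[0]):
        if not 0 <= after <= n_cols:
            raise GenerationError(f"insert block position {after} outside 0–{n_cols}")
        n_carriers = max(1, int(round(frac * (n_rows - 1))))
        carriers = rng.choice(np.arange(1, n_rows), size=n_carriers, replace=False)
        lengths = {int(r): int(rng.integers(1, length + 1)) for r in carriers}
        lengths[int(carriers[0])] = length  # guarantee one full-length insertion
        block = []
        for k in range(length):
            col = ["-"] * n_rows
            for r, ln in lengths.items():
                if k < ln:
                    col[r] = AA1[int(rng.integers(0, 20))]
            block.append(col)
        columns[after:after] = block
    rows = []
    for r in range(n_rows):
        ident = reference_id if r == 0 else f"seq{r:04d}"
        rows.append((ident, "".join(col[r] for col in columns)))
    msa = MultipleAlignment(rows)
    realized = np.array([
        sum(1 for ch in base[:, c] if ch == consensus[c]) / n_rows
        for c in range(n_cols)
    ])
    manifest = MsaManifest(consensus, cons, realized,
                           [tuple(b) for b in insert_blocks], reference_id)
    return msa, manifest
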