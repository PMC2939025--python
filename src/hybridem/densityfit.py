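"""Rigid placement of fragments into density and elastic-network flexible
fitting.

Rigid fitting runs a coarse exhaustive rotation grid with an FFT
translation scan, then refines the top candidates locally on the
normalized model–map cross-correlation. Candidate placements are screened
for linker feasibility: a placement can only be bridged to its sequence
anchors if every anchor span is at most 3.8 Å (the Cα virtual-bond
length) per missing residue plus one.

Flexible fitting moves Cα nodes up the density gradient under an elastic
network (uniform springs inside a distance cutoff) with an annealed
density-weight schedule and a per-step displacement cap; non-Cα atoms are
carried with their residue's Cα.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from hybridem.emmap import MapError, simulate_map
from hybridem.geometry import RigidTransform
from hybridem.spreconstruct import sphere_directions
from hybridem.structio import GridMap, StructureModel

LINKER_CA_STEP = 3.8  # Å per missing residue (+1)


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model–map cross-correlation
# ---------------------------------------------------------------------------

def model_map_cc(model, grid_map: GridMap, resolution: float,
                 mask_level: float = 0.1) -> float:
    """Normalized cross-correlation between a map and a simulated model map.

    The model (a :class:`StructureModel` or N×3 coordinates) is rendered
    on the experimental grid at the stated resolution; the correlation is
    computed over voxels where the simulated density exceeds
    ``mask_level`` × its maximum, and is invariant to affine rescaling of
    either map.
    """
    xyz = model.coords() if isinstance(model, StructureModel) else np.asarray(model, float)
    frac = (xyz - grid_map.origin) / grid_map.voxel_size
    shape = np.array(grid_map.values.shape)
    outside = np.any((frac < 0) | (frac > shape - 1), axis=1)
    if outside.any():
        raise FitError(f"{int(outside.sum())} atoms outside the map bounds")
    sim = simulate_map(xyz, resolution, grid_map.voxel_size,
                       grid_map.values.shape, origin=grid_map.origin)
    mask = sim.values > mask_level * sim.values.max()
    a = grid_map.values[mask].astype(float)
    b = sim.values[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


# ---------------------------------------------------------------------------
# Linker feasibility
# ---------------------------------------------------------------------------

@dataclass
class LinkerSpec:
    """One sequence linker between scaffold and placed fragment.

    ``missing_residues`` is the number of unmodeled residues bridging the
    scaffold anchor Cα to the fragment terminal Cα.
    """

    scaffold_residue: int
    fragment_residue: int
    missing_residues: int = 0
    scaffold_chain: str = "A"
    fragment_chain: str = "A"


@dataclass
class Placement:
    transform: RigidTransform
    cc: float
    linker_spans: list[float] = field(default_factory=list)
    feasible: bool = True


def linker_feasibility(scaffold: StructureModel, fragment: StructureModel,
                       transform: RigidTransform, linkers: Sequence[LinkerSpec],
                       ) -> tuple[list[float], bool]:
    """Anchor spans under a placement and whether all can be bridged.

    feasible ⇔ every span ≤ 3.8 Å × (missing residues + 1).
    """
    spans = []
    for lk in linkers:
        try:
            s_ca = scaffold.residue_ca(lk.scaffold_chain, lk.scaffold_residue).position
            f_ca = fragment.residue_ca(lk.fragment_chain, lk.fragment_residue).position
        except KeyError as exc:
            raise FitError(f"linker anchor missing: {exc}") from None
        placed = transform.apply(f_ca[None, :])[0]
        spans.append(float(np.linalg.norm(s_ca - placed)))
    feasible = all(
        span <= LINKER_CA_STEP * (lk.missing_residues + 1)
        for span, lk in zip(spans, linkers)
    )
    return spans, feasible


# ---------------------------------------------------------------------------
# Rigid fitting
# ---------------------------------------------------------------------------

class RigidFitResult(NamedTuple):
    feasible: list[Placement]
    infeasible: list[Placement]

    @property
    def best(self) -> Placement:
        if self.feasible:
            return self.feasible[0]
        if self.infeasible:
            return self.infeasible[0]
        raise FitError("no placements found")


def _rotation_grid(angular_step: float) -> list[np.ndarray]:
    """Exhaustive SO(3) grid: sphere directions × in-plane angles."""
    mats = []
    for phi, theta in sphere_directions(angular_step):
        for psi in np.arange(0.0, 360.0, angular_step):
            mats.append(Rotation.from_euler(
                "ZYZ", [phi, theta, psi], degrees=True).as_matrix())
    return mats


def _cc_objective(params: np.ndarray, xyz0: np.ndarray, center: np.ndarray,
                  grid_map: GridMap, resolution: float) -> float:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    xyz = (xyz0 - center) @ rot.T + center + params[3:]
    try:
        return -model_map_cc(xyz, grid_map, resolution)
    except FitError:
        return 1.0  # out of bounds: worst score


def refine_placement(fragment: StructureModel, grid_map: GridMap,
                     start: RigidTransform, resolution: float) -> RigidTransform:
    """Local (Nelder–Mead) refinement of a placement on the map CC."""
    xyz0 = fragment.coords()
    center = xyz0.mean(axis=0)
    rv0 = Rotation.from_matrix(start.rotation).as_rotvec()
    t0 = start.apply(center[None, :])[0] - center
    x0 = np.concatenate([rv0, t0])
    res = minimize(_cc_objective, x0, args=(xyz0, center, grid_map, resolution),
                   method="Nelder-Mead",
                   options={"maxiter": 300, "xatol": 1e-3, "fatol": 1e-6})
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
    # x ↦ R (x − c) + c + t
    return RigidTransform(rot, center + res.x[3:] - rot @ center)


def rigid_fit(fragment: StructureModel, grid_map: GridMap, resolution: float,
              angular_step: float = 30.0,
              scaffold: StructureModel | None = None,
              linkers: Sequence[LinkerSpec] = (),
              n_refine: int = 5, seed: int = 0) -> RigidFitResult:
    """Exhaustive coarse search + local refinement of a fragment in density.

    For every rotation on the grid the best translation comes from an FFT
    cross-correlation scan; the ``n_refine`` best candidates are refined
    locally and screened for linker feasibility against the scaffold.
    Feasible placements are ranked by CC; infeasible ones are kept in a
    separate ranked list so a failed search is never silent.
    """
    del seed  # search is fully deterministic; kept for interface stability
    xyz0 = fragment.coords()
    center = xyz0.mean(axis=0)
    shape = grid_map.values.shape
    target_f = np.fft.fftn(grid_map.values)
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []
    for rot in _rotation_grid(angular_step):
        xyz = (xyz0 - center) @ rot.T
        # render the rotated fragment centered in the box, then FFT-scan
        box_center = grid_map.origin + grid_map.voxel_size * (np.array(shape) - 1) / 2
        try:
            sim = simulate_map(xyz + box_center, resolution, grid_map.voxel_size,
                               shape, origin=grid_map.origin)
        except MapError:
            continue  # rotated fragment exceeds the box; skip this rotation
        cc = np.fft.ifftn(target_f * np.conj(np.fft.fftn(sim.values))).real
        ij = np.unravel_index(np.argmax(cc), shape)
        shift_vox = np.array([(s + n // 2) % n - n // 2 for s, n in zip(ij, shape)])
        trans = box_center + shift_vox * grid_map.voxel_size
        candidates.append((float(cc[ij]), rot, trans))
    candidates.sort(key=lambda c: -c[0])
    from hybridem.geometry import rotation_angle

    placements: list[Placement] = []
    for _, rot, trans in candidates[:max(n_refine, 1)]:
        start = RigidTransform(rot, trans - rot @ center)
        refined = refine_placement(fragment, grid_map, start, resolution)
        try:
            cc = model_map_cc(fragment.transformed(refined), grid_map, resolution)
        except FitError:
            continue
        duplicate = any(
            rotation_angle(refined, p.transform) < 5.0
            and np.linalg.norm(refined.apply(center[None])[0]
                               - p.transform.apply(center[None])[0]) < grid_map.voxel_size
            for p in placements)
        if duplicate:
            continue
        spans, ok = ([], True)
        if linkers:
            if scaffold is None:
                raise FitError("linkers given without a scaffold")
            spans, ok = linker_feasibility(scaffold, fragment, refined, linkers)
        placements.append(Placement(refined, cc, spans, ok))
    feasible = sorted([p for p in placements if p.feasible], key=lambda p: -p.cc)
    infeasible = sorted([p for p in placements if not p.feasible], key=lambda p: -p.cc)
    return RigidFitResult(feasible, infeasible)


# ---------------------------------------------------------------------------
# Flexible fitting
# ---------------------------------------------------------------------------

@dataclass
class ENMParams:
    """Elastic-network flexible-fitting parameters.

    ``cutoff`` (Å) is the Cα contact distance defining springs;
    ``weights`` is the annealed density-weight schedule (one gradient
    phase per weight); ``step_cap`` caps per-node displacement per step.
    """

    cutoff: float = 12.0
    spring_k: float = 1.0
    weights: tuple[float, ...] = (0.5, 1.0, 1.5)
    step_cap: float = 0.3
    max_steps: int = 300

    def __post_init__(self) -> None:
        if not self.cutoff > LINKER_CA_STEP:
            raise FitError(f"ENM cutoff must exceed {LINKER_CA_STEP} Å")
        if any(w <= 0 for w in self.weights):
            raise FitError("density weights must be positive")


class FlexFitDiagnostics(NamedTuple):
    cc_initial: float
    cc_final: float
    cc_trajectory: list[float]
    strain_initial: float
    strain_final: float


def _enm_springs(ca_xyz: np.ndarray, cutoff: float):
    tree = cKDTree(ca_xyz)
    pairs = np.array(sorted(tree.query_pairs(cutoff)))
    if len(pairs) == 0:
        raise FitError("no ENM springs — cutoff too small")
    n = len(ca_xyz)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise FitError(
            f"elastic network is disconnected: {n_comp} components of sizes "
            f"{sorted(sizes.tolist(), reverse=True)}")
    rest = np.linalg.norm(ca_xyz[pairs[:, 0]] - ca_xyz[pairs[:, 1]], axis=1)
    return pairs, rest


def _strain_energy(xyz: np.ndarray, pairs: np.ndarray, rest: np.ndarray,
                   k: float) -> float:
    d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    return float(0.5 * k * np.sum((d - rest) ** 2))


def _spring_forces(xyz: np.ndarray, pairs: np.ndarray, rest: np.ndarray,
                   k: float) -> np.ndarray:
    delta = xyz[pairs[:, 0]] - xyz[pairs[:, 1]]
    d = np.linalg.norm(delta, axis=1)
    d[d < 1e-9] = 1e-9
    f = -k * (d - rest)[:, None] * delta / d[:, None]
    out = np.zeros_like(xyz)
    np.add.at(out, pairs[:, 0], f)
    np.add.at(out, pairs[:, 1], -f)
    return out


def _density_gradient_interp(grid_map: GridMap):
    g = np.gradient(grid_map.values.astype(float), grid_map.voxel_size)

    def grad_at(xyz: np.ndarray) -> np.ndarray:
        frac = ((xyz - grid_map.origin) / grid_map.voxel_size).T
        return np.stack([ndimage.map_coordinates(gi, frac, order=1, mode="nearest")
                         for gi in g], axis=1)

    return grad_at


def flexible_fit(model: StructureModel, grid_map: GridMap,
                 params: ENMParams | None = None,
                 freeze: Sequence[int] | None = None,
                 resolution: float = 15.0, seed: int = 0,
                 ) -> tuple[StructureModel, FlexFitDiagnostics]:
    """Elastic-network restrained fitting of a model into density.

    Cα nodes ascend the interpolated density gradient against the elastic
    strain of the network, with a per-step displacement cap; residues
    listed in ``freeze`` (residue numbers, any chain) do not move, and
    non-Cα atoms ride with their residue's Cα displacement. The returned
    model is the best-CC snapshot along the trajectory, so the final CC
    is never below the initial one.
    """
    del seed  # deterministic gradient scheme; kept for interface stability
    params = params or ENMParams()
    ca_model = model.ca_only()
    if len(ca_model) < 2:
        raise FitError("flexible_fit needs at least 2 Cα atoms")
    ca_xyz = ca_model.coords()
    frozen = np.zeros(len(ca_model), dtype=bool)
    if freeze is not None:
        freeze_set = set(freeze)
        frozen = np.array([a.residue_number in freeze_set for a in ca_model.atoms])
    pairs, rest = _enm_springs(ca_xyz, params.cutoff)
    norm_map = grid_map.sigma_normalized()
    # σ-normalized density puts the gradient on the same scale as the
    # unit-spring elastic forces, so the weight schedule is meaningful
    grad_at = _density_gradient_interp(norm_map)

    def cc_of(xyz: np.ndarray) -> float:
        try:
            return model_map_cc(xyz, norm_map, resolution)
        except FitError:
            return -1.0

    cc0 = cc_of(ca_xyz)
    strain0 = _strain_energy(ca_xyz, pairs, rest, params.spring_k)
    best_xyz, best_cc = ca_xyz.copy(), cc0
    traj = [cc0]
    xyz = ca_xyz.copy()
    steps_per_phase = max(1, params.max_steps // len(params.weights))
    check_every = 10
    for w in params.weights:
        for step in range(steps_per_phase):
            force = w * grad_at(xyz) + _spring_forces(xyz, pairs, rest, params.spring_k)
            norms = np.linalg.norm(force, axis=1, keepdims=True)
            if float(norms.max()) < 1e-12:
                break
            # soft per-node normalization: strong-force nodes move close to
            # step_cap, weak-force nodes proportionally less — keeps the
            # ascent stable without a global scale choice
            disp = params.step_cap * force / (norms + np.percentile(norms, 50))
            disp[frozen] = 0.0
            xyz = xyz + disp
            if (step + 1) % check_every == 0:
                cc = cc_of(xyz)
                traj.append(cc)
                if cc > best_cc:
                    best_cc, best_xyz = cc, xyz.copy()
    strain1 = _strain_energy(best_xyz, pairs, rest, params.spring_k)
    # carry all atoms with their residue's Cα displacement
    disp_by_res = {
        (a.chain_id, a.residue_number): best_xyz[i] - ca_xyz[i]
        for i, a in enumerate(ca_model.atoms)
    }
    out = model.copy()
    for a in out.atoms:
        d = disp_by_res.get((a.chain_id, a.residue_number))
        if d is not None:
            a.position = a.position + d
    return out, FlexFitDiagnostics(cc0, best_cc, traj, strain0, strain1)
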