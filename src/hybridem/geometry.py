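"""Rigid-body mathematics and structural measurements.

Superposition uses the least-squares Kabsch solution (via
``scipy.spatial.transform.Rotation.align_vectors``) with reflections
rejected; solvent-accessible surface areas use deterministic Shrake–Rupley
point sampling on a Fibonacci sphere so repeated runs give identical
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from hybridem.structio import StructureModel

# Community-default van der Waals radii (Å)
DEFAULT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "MG": 1.73, "ZN": 1.39, "FE": 1.40,
}


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation 3×3 with det +1, t in Å)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise GeometryError("RigidTransform needs a 3×3 rotation and a 3-vector")
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) > 1e-6:
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise GeometryError("reflection (det −1) is not a rigid motion")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotvec(cls, rotvec_deg: Sequence[float], translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_flat(self) -> np.ndarray:
        """12 numbers: rotation rows then translation."""
        return np.concatenate([self.rotation.ravel(), self.translation])


@dataclass(frozen=True)
class DomainRange:
    """Inclusive author-numbered residue interval on one chain."""

    chain_id: str
    first_residue: int
    last_residue: int
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise GeometryError(
                f"invalid range {self.first_residue}–{self.last_residue}: first > last"
            )

    def __len__(self) -> int:
        return self.last_residue - self.first_residue + 1

    def select(self, model: StructureModel) -> StructureModel:
        return model.select(self.chain_id, self.first_residue, self.last_residue,
                            atom_names=self.atom_names)


def interval_length(domain_range: DomainRange) -> int:
    """Residue count of an inclusive author-numbered interval."""
    return len(domain_range)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

class SuperpositionResult(NamedTuple):
    transform: RigidTransform
    rmsd: float
    degenerate: bool


def _coords(x) -> np.ndarray:
    if isinstance(x, StructureModel):
        return x.coords()
    return np.asarray(x, dtype=float)


def superpose(mobile, reference) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Point lists must be in correspondence order with ≥ 3 points. The
    returned transform maps mobile coordinates onto the reference frame;
    ``rmsd`` is evaluated after applying it. Collinear point sets are
    solved but flagged ``degenerate`` (the rotation about the line is
    unconstrained).
    """
    mob, ref = _coords(mobile), _coords(reference)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError(f"shape mismatch: mobile {mob.shape} vs reference {ref.shape}")
    if len(mob) < 3:
        raise GeometryError(f"need ≥ 3 points to superpose, got {len(mob)}")
    mob_c, ref_c = mob.mean(axis=0), ref.mean(axis=0)
    a, b = ref - ref_c, mob - mob_c
    # rank < 2 ⇒ the points lie on a line (or a point)
    degenerate = bool(np.linalg.matrix_rank(b, tol=1e-8) < 2
                      or np.linalg.matrix_rank(a, tol=1e-8) < 2)
    import warnings

    with warnings.catch_warnings():
        if degenerate:  # we flag degeneracy ourselves
            warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(a, b)  # proper rotation, reflection rejected
    transform = RigidTransform(rot.as_matrix(), ref_c - rot.as_matrix() @ mob_c)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mob) - ref) ** 2, axis=1))))
    return SuperpositionResult(transform, rmsd, degenerate)


def rotation_angle(a: RigidTransform | np.ndarray, b: RigidTransform | np.ndarray) -> float:
    """Magnitude in degrees of the relative rotation between two transforms.

    Symmetric in its arguments; the result lies in [0°, 180°].
    """
    ra = a.rotation if isinstance(a, RigidTransform) else np.asarray(a, dtype=float)
    rb = b.rotation if isinstance(b, RigidTransform) else np.asarray(b, dtype=float)
    rel = rb @ ra.T
    cos = np.clip((np.trace(rel) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class MinDistanceResult(NamedTuple):
    distance: float
    atom_a: object
    atom_b: object


def min_distance(a: StructureModel, b: StructureModel) -> MinDistanceResult:
    """Exact global minimum distance over all cross pairs.

    Ties (within 1e-9 Å) break to the first pair in file order.
    """
    if len(a) == 0 or len(b) == 0:
        side = "first" if len(a) == 0 else "second"
        raise GeometryError(f"min_distance: the {side} selection is empty")
    pa, pb = a.coords(), b.coords()
    if pa.shape[0] * pb.shape[0] <= 4_000_000:
        d = cdist(pa, pb)
        best = d.min()
        ia, ib = np.argwhere(d <= best + 1e-9)[0]
    else:
        tree = cKDTree(pb)
        dist, idx = tree.query(pa)
        ia = int(np.argmin(dist))
        best, ib = dist[ia], idx[ia]
    return MinDistanceResult(float(np.linalg.norm(pa[ia] - pb[ib])), a.atoms[ia], b.atoms[ib])


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------

@dataclass
class SasaParams:
    probe_radius: float = 1.4
    points_per_atom: int = 960
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if not self.probe_radius > 0:
            raise GeometryError("probe_radius must be > 0")
        if self.points_per_atom < 12:
            raise GeometryError("points_per_atom must be ≥ 12")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, quasi-uniform unit vectors."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(model: StructureModel, params: SasaParams) -> np.ndarray:
    radii = []
    unknown = []
    for a in model.atoms:
        key = (a.element or a.atom_name[:1]).upper()
        if key not in params.radii:
            unknown.append(f"{a.atom_name} {a.chain_id}{a.residue_number} ({key!r})")
        else:
            radii.append(params.radii[key])
    if unknown:
        raise GeometryError(f"no vdW radius for atoms: {unknown}")
    return np.array(radii)


def sasa(model: StructureModel, params: SasaParams | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    The sampling point set is deterministic, so reruns are bit-identical.
    """
    params = params or SasaParams()
    if len(model) == 0:
        return np.zeros(0)
    xyz = model.coords()
    radii = _atom_radii(model, params) + params.probe_radius
    sphere = _fibonacci_sphere(params.points_per_atom)
    tree = cKDTree(xyz)
    max_r = radii.max()
    areas = np.zeros(len(model))
    for i in range(len(model)):
        pts = xyz[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(xyz[i], radii[i] + max_r) if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas


class BuriedAreaResult(NamedTuple):
    total: float       # SASA(a) + SASA(b) − SASA(a∪b)
    one_sided: float   # total / 2


def buried_area(model: StructureModel, group_a, group_b,
                params: SasaParams | None = None) -> BuriedAreaResult:
    """Surface area buried between two disjoint atom groups (Å²).

    Groups may be :class:`DomainRange` selections on ``model`` or explicit
    :class:`StructureModel` subsets. Both the total buried area
    (SASA(a)+SASA(b)−SASA(a∪b)) and the one-sided value (÷2) are returned
    because either convention appears in the literature.
    """
    params = params or SasaParams()
    a = group_a.select(model) if isinstance(group_a, DomainRange) else group_a
    b = group_b.select(model) if isinstance(group_b, DomainRange) else group_b
    keys_a = {(x.chain_id, x.residue_number, x.insertion_code, x.atom_name) for x in a}
    keys_b = {(x.chain_id, x.residue_number, x.insertion_code, x.atom_name) for x in b}
    if keys_a & keys_b:
        raise GeometryError(f"groups overlap on {len(keys_a & keys_b)} atoms")
    union = StructureModel(list(a.atoms) + list(b.atoms))
    total = float(sasa(a, params).sum() + sasa(b, params).sum() - sasa(union, params).sum())
    return BuriedAreaResult(total, total / 2.0)


# ---------------------------------------------------------------------------
# Shape measurements
# ---------------------------------------------------------------------------

class ExtentResult(NamedTuple):
    length: float
    diameter: float
    degenerate: bool


def domain_extent(selection) -> ExtentResult:
    """Principal-axis length and mean transverse diameter of a point cloud.

    Length is the extent along the largest principal axis of the centered
    coordinates; the diameter is the mean over the two minor axes of twice
    the maximum radial distance.
    """
    xyz = _coords(selection)
    if len(xyz) < 3:
        raise GeometryError(f"domain_extent needs ≥ 3 atoms, got {len(xyz)}")
    centered = xyz - xyz.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    length = float(proj[:, 0].max() - proj[:, 0].min())
    diameter = float(np.mean([2.0 * np.abs(proj[:, k]).max() for k in (1, 2)]))
    degenerate = bool(s[1] < 1e-8 * max(s[0], 1.0))
    return ExtentResult(length, diameter, degenerate)


def reach(selection, anchor_point: np.ndarray) -> float:
    """Maximum distance (Å) of any point in the selection from the anchor.

    For a lineage-specific insert the natural anchor is the midpoint of
    the Cα atoms of its two boundary residues.
    """
    xyz = _coords(selection)
    if len(xyz) == 0:
        raise GeometryError("reach: empty selection")
    anchor = np.asarray(anchor_point, dtype=float)
    return float(np.linalg.norm(xyz - anchor, axis=1).max())


def insert_anchor(model: StructureModel, chain_id: str,
                  first_residue: int, last_residue: int) -> np.ndarray:
    """Midpoint of the Cα atoms of an insert's two boundary residues."""
    ca1 = model.residue_ca(chain_id, first_residue).position
    ca2 = model.residue_ca(chain_id, last_residue).position
    return (ca1 + ca2) / 2.0


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def measurements_table(rows: Sequence[dict], destination=None):
    """Collect measurement dicts (selection, value, units, …) into a table."""
    import pandas as pd

    df = pd.DataFrame(list(rows))
    if destination is not None:
        df.to_csv(destination, sep="\t", index=False)
    return df
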