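"""Readers and writers for the standard formats the pipeline touches.

Coordinates are in Å in a right-handed frame; author residue numbering is
kept verbatim because every domain boundary in this package is addressed by
author numbers. PDB I/O works directly on the fixed-column v3.3 layout so
that parse errors can name the offending line and coordinate overflow of
the 8.3 column is an explicit error rather than silent truncation.
Density maps go through gemmi (MRC/CCP4 2014, mode 2); alignments go
through Biopython (FASTA and GCG MSF).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GAP_CHARS = {"-", ".", "~"}


class ParseError(ValueError):
    """Raised when a fixed-column record cannot be parsed."""


class OverflowWriteError(ValueError):
    """Raised when a value does not fit its fixed-width PDB column."""


# ---------------------------------------------------------------------------
# Atomic structures
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``residue_number`` is the author number and survives a read→write
    roundtrip exactly. ``het`` marks HETATM records (ions, ligands), which
    are excluded from protein selections by default.
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    insertion_code: str = ""
    element: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"atom {self.atom_name} {self.chain_id}{self.residue_number}: "
                f"position must be a finite 3-vector, got {self.position!r}"
            )

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


class StructureModel:
    """Ordered collection of atoms with selection by chain/residue range.

    Selection preserves file order; an empty selection is a legal (empty)
    model, distinct from an error.
    """

    def __init__(self, atoms: Iterable[AtomRecord] = ()):
        self.atoms: list[AtomRecord] = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def copy(self) -> "StructureModel":
        return StructureModel(a.copy() for a in self.atoms)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def coords(self) -> np.ndarray:
        """N×3 array of positions in file order (empty → shape (0, 3))."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape {(len(self.atoms), 3)}, got {xyz.shape}")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()

    def select(
        self,
        chain_id: str | None = None,
        first_residue: int | None = None,
        last_residue: int | None = None,
        atom_names: Sequence[str] | None = None,
        include_het: bool = False,
        insertion_code: str | None = None,
    ) -> "StructureModel":
        """Atoms matching the filters, in file order.

        Insertion codes are ignored unless ``insertion_code`` is given
        explicitly. HETATM records are excluded unless ``include_het``.
        """
        names = {n.strip() for n in atom_names} if atom_names is not None else None
        out = []
        for a in self.atoms:
            if a.het and not include_het:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if first_residue is not None and a.residue_number < first_residue:
                continue
            if last_residue is not None and a.residue_number > last_residue:
                continue
            if names is not None and a.atom_name.strip() not in names:
                continue
            if insertion_code is not None and a.insertion_code != insertion_code:
                continue
            out.append(a)
        return StructureModel(out)

    def ca_only(self, chain_id: str | None = None) -> "StructureModel":
        return self.select(chain_id=chain_id, atom_names=["CA"])

    def residue_ca(self, chain_id: str, residue_number: int) -> AtomRecord:
        """The Cα of one residue; KeyError if absent."""
        sel = self.select(chain_id, residue_number, residue_number, atom_names=["CA"])
        if not sel.atoms:
            raise KeyError(f"no CA atom for {chain_id}{residue_number}")
        return sel.atoms[0]

    def residue_numbers(self, chain_id: str | None = None) -> list[int]:
        """Distinct residue numbers in file order (protein atoms only)."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            if a.het:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            seen.setdefault((a.chain_id, a.residue_number))
        return [r for (_, r) in seen]

    def transformed(self, transform) -> "StructureModel":
        """New model with ``transform`` (geometry.RigidTransform) applied."""
        out = self.copy()
        if len(out):
            out.set_coords(transform.apply(out.coords()))
        return out


# -- PDB fixed-column parsing ------------------------------------------------

def _parse_atom_line(line: str, lineno: int, het: bool) -> AtomRecord:
    line = line.rstrip("\n").ljust(80)
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        resnum = int(line[22:26])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed fixed-column field ({exc})") from None
    occ_s, b_s = line[54:60].strip(), line[60:66].strip()
    try:
        occ = float(occ_s) if occ_s else 1.0
        bfac = float(b_s) if b_s else 0.0
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed occupancy/B-factor ({exc})") from None
    element = line[76:78].strip()
    if not element:
        # fall back on the first letter of the atom name, PDB v2 style
        element = line[12:16].strip().lstrip("0123456789")[:1]
    return AtomRecord(
        chain_id=line[21].strip(),
        residue_number=resnum,
        insertion_code=line[26].strip(),
        residue_name=line[17:20].strip(),
        atom_name=line[12:16].strip(),
        element=element,
        position=np.array([x, y, z]),
        occupancy=occ,
        b_factor=bfac,
        het=het,
    )


def read_structure(source: str | Path) -> StructureModel:
    """Parse PDB ATOM/HETATM records into a :class:`StructureModel`.

    ``source`` may be a path or PDB-format text. Only the first MODEL block
    is read; further blocks are skipped with a logged warning.
    """
    text = _as_text(source)
    atoms: list[AtomRecord] = []
    in_skipped_model = False
    model_count = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            model_count += 1
            if model_count > 1:
                in_skipped_model = True
                logger.warning("multiple MODEL blocks; keeping only the first")
        elif rec == "ENDMDL":
            continue
        elif rec in ("ATOM", "HETATM") and not in_skipped_model:
            atoms.append(_parse_atom_line(line, lineno, het=rec == "HETATM"))
    return StructureModel(atoms)


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    for label, v in (("x", a.position[0]), ("y", a.position[1]), ("z", a.position[2])):
        s = f"{v:8.3f}"
        if len(s) > 8:
            raise OverflowWriteError(
                f"coordinate {label}={v} of atom {a.atom_name} "
                f"{a.chain_id}{a.residue_number} overflows the 8.3 PDB column"
            )
    if not (-999 <= a.residue_number <= 9999):
        raise OverflowWriteError(
            f"residue number {a.residue_number} overflows the 4-digit PDB column"
        )
    name = a.atom_name
    # standard PDB padding: 1-letter elements start in column 14
    name_f = f" {name:<3s}" if len(name) < 4 and len(a.element) < 2 else f"{name:<4s}"
    rec = "HETATM" if a.het else "ATOM  "
    return (
        f"{rec}{serial % 100000:5d} {name_f[:4]}{'':1s}{a.residue_name:>3s} "
        f"{(a.chain_id or 'A')[:1]}{a.residue_number:4d}{(a.insertion_code or ' ')[:1]}"
        f"   {a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
    )


def write_structure(model: StructureModel, destination: str | Path | None = None) -> str:
    """Write PDB-format text (and to ``destination`` when given).

    Coordinates are emitted to 3 decimals; values that do not fit the 8.3
    column raise :class:`OverflowWriteError`.
    """
    lines = ["REMARK   1 WRITTEN BY HYBRIDEM"]
    prev_chain = None
    serial = 0
    for a in model.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        serial += 1
        lines.append(_format_atom_line(a, serial))
        prev_chain = a.chain_id
    if model.atoms:
        lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if destination is not None:
        Path(destination).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

@dataclass
class GridMap:
    """3-D scalar density on a regular grid.

    ``values[i, j, k]`` sits at ``origin + voxel_size * (i, j, k)`` Å; the
    axis order is X/Y/Z (column/row/section permuted to this convention on
    read). The voxel size is isotropic.
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.values.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "GridMap":
        return GridMap(self.values.copy(), self.voxel_size, self.origin.copy())

    def sigma_normalized(self) -> "GridMap":
        """Map rescaled to zero mean, unit standard deviation."""
        sd = float(self.values.std())
        if sd == 0:
            raise ValueError("cannot σ-normalize a constant map")
        out = self.copy()
        out.values = (self.values - self.values.mean()) / sd
        return out

    def voxel_to_xyz(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + self.voxel_size * np.asarray(ijk, dtype=float)

    def xyz_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size


class MapFormatError(ValueError):
    """Raised for unsupported MRC modes or non-isotropic geometry."""


def read_map(source: str | Path) -> GridMap:
    """Read an MRC/CCP4 mode-2 map via gemmi, permuting axes to X/Y/Z."""
    import gemmi

    m = gemmi.read_ccp4_map(str(source))
    mode = m.header_i32(4)
    if mode != 2:
        raise MapFormatError(f"unsupported MRC mode {mode}; only mode 2 (float32) is read")
    # permute column/row/section to X/Y/Z
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    nx, ny, nz = values.shape
    vx, vy, vz = cell.a / nx, cell.b / ny, cell.c / nz
    if not (np.isclose(vx, vy, rtol=1e-4) and np.isclose(vx, vz, rtol=1e-4)):
        raise MapFormatError(
            f"non-isotropic voxels ({vx:.4g}, {vy:.4g}, {vz:.4g}) Å; resample before use"
        )
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if not np.any(origin):
        # fall back on NXSTART-style origin
        start = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = start * vx
    return GridMap(values.astype(np.float32), float(vx), origin)


def write_map(grid_map: GridMap, destination: str | Path) -> None:
    """Write MRC mode 2; values roundtrip bit-exactly (float32 payload)."""
    import gemmi

    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid_map.values, dtype=np.float32))
    n = grid_map.values.shape
    v = grid_map.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(n[0] * v, n[1] * v, n[2] * v, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for i, val in zip((50, 51, 52), grid_map.origin):
        m.set_header_float(i, float(val))
    m.write_ccp4_map(str(destination))


# ---------------------------------------------------------------------------
# Multiple alignments
# ---------------------------------------------------------------------------

class AlignmentError(ValueError):
    pass


@dataclass
class MultipleAlignment:
    """Rows of gapped sequences; MSF gap characters are normalized to '-'."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        norm = []
        for ident, seq in self.rows:
            norm.append((ident, "".join("-" if c in GAP_CHARS else c.upper() for c in seq)))
        self.rows = norm
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence identifiers: {dup}")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            ref = len(self.rows[0][1])
            bad = [i for i, s in self.rows if len(s) != ref]
            raise AlignmentError(f"ragged alignment rows: {bad}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, identifier: str) -> str:
        for ident, seq in self.rows:
            if ident == identifier:
                return seq
        raise KeyError(f"no row named {identifier!r}")

    def column(self, index: int) -> str:
        return "".join(seq[index] for _, seq in self.rows)


def read_alignment(source: str | Path) -> MultipleAlignment:
    """Read a FASTA or GCG MSF multiple alignment (format auto-detected)."""
    text = _as_text(source)
    stripped = text.lstrip()
    if stripped.startswith(">"):
        return _read_fasta_alignment(text)
    if "MSF" in text.split("//")[0] or stripped.lower().startswith("!!"):
        return _read_msf_alignment(text)
    raise AlignmentError("unrecognized alignment format (expected FASTA or GCG MSF)")


def _read_fasta_alignment(text: str) -> MultipleAlignment:
    from Bio import SeqIO

    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise AlignmentError("no sequences found in FASTA input")
    return MultipleAlignment([(r.id, str(r.seq)) for r in records])


def _read_msf_alignment(text: str) -> MultipleAlignment:
    from Bio import AlignIO

    try:
        aln = AlignIO.read(io.StringIO(text), "msf")
    except ValueError as exc:
        raise AlignmentError(f"MSF parse failed: {exc}") from None
    return MultipleAlignment([(r.id, str(r.seq)) for r in aln])


def write_alignment_fasta(msa: MultipleAlignment, destination: str | Path | None = None) -> str:
    text = "".join(f">{ident}\n{seq}\n" for ident, seq in msa.rows)
    if destination is not None:
        Path(destination).write_text(text)
    return text


# ---------------------------------------------------------------------------

def _as_text(source: str | Path) -> str:
    """Accept a path or literal file content."""
    if isinstance(source, Path):
        return source.read_text()
    if "\n" not in source and len(source) < 4096:
        p = Path(source)
        if p.exists():
            return p.read_text()
    return source
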