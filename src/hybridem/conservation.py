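"""Column-level conservation analysis of insert alignments.

Positions are addressed by author residue numbers on a designated
reference row (the residue number minus a configurable offset gives the
index among the row's non-gap characters). The per-column "% of
sequences" convention counts gap rows in the denominator — a gapped
sequence does not conserve the residue — with the gap-excluded variant
also reported.

The Blosum62 information score here is a rescaled mean-pairwise
similarity: exact at the endpoints (a gap-free identical column scores 1,
a column pairing the most dissimilar residues scores 0) and weighted by
coverage, standing in for the score popularized by alignment viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from hybridem.structio import MultipleAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConservationError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueClassSpec:
    """A named residue class, e.g. basic = {R, K}."""

    name: str
    residues: frozenset[str]

    def __post_init__(self) -> None:
        letters = {r.upper() for r in self.residues}
        if not letters or not letters <= set(AMINO_ACIDS):
            raise ConservationError(
                f"residue class must be a non-empty subset of the 20 amino acids, "
                f"got {sorted(self.residues)}")
        object.__setattr__(self, "residues", frozenset(letters))


BASIC = ResidueClassSpec("basic", frozenset("RK"))
ACIDIC = ResidueClassSpec("acidic", frozenset("DE"))


# ---------------------------------------------------------------------------
# Reference-row mapping
# ---------------------------------------------------------------------------

def map_residue_to_column(msa: MultipleAlignment, reference_id: str,
                          residue_number: int, numbering_offset: int = 0) -> int:
    """Column index (0-based) of an author-numbered reference residue.

    The reference row's k-th non-gap character corresponds to residue
    number ``numbering_offset + k`` (k counted from 1), i.e. the column
    returned holds the (residue_number − numbering_offset)-th non-gap
    character of the reference row.
    """
    row = msa.row(reference_id)
    ordinal = residue_number - numbering_offset
    n_nongap = sum(1 for c in row if c != "-")
    if not 1 <= ordinal <= n_nongap:
        raise ConservationError(
            f"residue {residue_number} outside the reference span "
            f"(valid: {numbering_offset + 1}–{numbering_offset + n_nongap})")
    count = 0
    for col, c in enumerate(row):
        if c != "-":
            count += 1
            if count == ordinal:
                return col
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Class fractions
# ---------------------------------------------------------------------------

class ClassFractionResult(NamedTuple):
    fraction: float           # gaps counted in the denominator
    fraction_nongap: float    # gap rows excluded
    n_in_class: int
    n_rows: int
    n_nongap: int


def class_fraction(msa: MultipleAlignment, column: int,
                   spec: ResidueClassSpec) -> ClassFractionResult:
    """Fraction of sequences whose character at ``column`` is in the class.

    The headline fraction counts gap rows in the denominator; the
    gap-excluded variant is reported alongside.
    """
    col = msa.column(column)
    n_in = sum(1 for c in col if c in spec.residues)
    n_nongap = sum(1 for c in col if c != "-")
    return ClassFractionResult(
        n_in / len(col),
        n_in / n_nongap if n_nongap else 0.0,
        n_in, len(col), n_nongap)


# ---------------------------------------------------------------------------
# Blosum62 information score
# ---------------------------------------------------------------------------

def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


class ColumnScore(NamedTuple):
    score: float | None       # None when < 2 non-gap rows
    coverage: float
    consensus: str            # most frequent non-gap residue ('-' if none)


def blosum_information(msa: MultipleAlignment, column: int) -> ColumnScore:
    """Rescaled mean-pairwise Blosum62 similarity of a column, × coverage.

    Self-identical columns of any residue score 1 before the coverage
    factor; the matrix minimum maps to 0. Columns with fewer than two
    non-gap rows are undefined (score ``None``).
    """
    mat = _blosum62()
    col = msa.column(column)
    residues = [c for c in col if c != "-" and c in mat.alphabet]
    coverage = sum(1 for c in col if c != "-") / len(col)
    if len(residues) < 2:
        return ColumnScore(None, coverage, _consensus(col))
    lo = float(np.min(mat))
    total, count = 0.0, 0
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            a, b = residues[i], residues[j]
            # normalize each pair against its self-similarity ceiling
            hi = min(mat[a, a], mat[b, b])
            total += (mat[a, b] - lo) / (hi - lo)
            count += 1
    return ColumnScore(coverage * total / count, coverage, _consensus(col))


def _consensus(col: str) -> str:
    counts: dict[str, int] = {}
    for c in col:
        if c != "-":
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        return "-"
    return max(sorted(counts), key=lambda c: counts[c])


def column_profile(msa: MultipleAlignment) -> list[ColumnScore]:
    """Blosum information score, coverage and consensus for every column."""
    return [blosum_information(msa, c) for c in range(msa.n_columns)]


# ---------------------------------------------------------------------------
# Insertion-location profiles
# ---------------------------------------------------------------------------

class InsertionSite(NamedTuple):
    reference_position: int   # author-numbered residue preceding the insertion
    max_length: int           # longest insertion any row carries there


def insertion_profile(msa: MultipleAlignment, reference_id: str,
                      numbering_offset: int = 0) -> list[InsertionSite]:
    """Insertions relative to the reference row.

    For each maximal run of reference-row gap columns, reports the
    author-numbered reference position immediately preceding the run and
    the maximum number of non-gap characters any single row places in it.
    """
    row = msa.row(reference_id)
    sites: list[InsertionSite] = []
    pos = numbering_offset  # author number of the last seen reference residue
    col = 0
    n = len(row)
    while col < n:
        if row[col] != "-":
            pos += 1
            col += 1
            continue
        run_start = col
        while col < n and row[col] == "-":
            col += 1
        max_len = 0
        for _, seq in msa.rows:
            length = sum(1 for c in seq[run_start:col] if c != "-")
            max_len = max(max_len, length)
        if max_len > 0:
            sites.append(InsertionSite(pos, max_len))
    return sites


def profile_table(msa: MultipleAlignment, reference_id: str,
                  numbering_offset: int = 0, destination=None):
    """Per-column table: score, coverage, consensus, reference numbering."""
    import pandas as pd

    row = msa.row(reference_id)
    ref_num, nums = numbering_offset, []
    for c in row:
        if c != "-":
            ref_num += 1
            nums.append(ref_num)
        else:
            nums.append(None)
    prof = column_profile(msa)
    df = pd.DataFrame({
        "column": range(msa.n_columns),
        "reference_residue": nums,
        "score": [p.score for p in prof],
        "coverage": [p.coverage for p in prof],
        "consensus": [p.consensus for p in prof],
    })
    if destination is not None:
        df.to_csv(destination, sep="\t", index=False)
    return df
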