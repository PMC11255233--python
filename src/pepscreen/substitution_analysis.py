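"""Position × residue intensity matrices for substitution-scanned parents.

For a parent peptide of length L, the matrix has one row per position and
one column per amino acid; cell (pos, aa) holds the measured Int. of the
variant with *aa* at *pos*, and the parent's own Int. fills the diagonal
cells (pos, parent[pos]). Critical substitutions are cells at or below a
repulsion threshold — by default the empty-spot floor (blank median plus
two blank MADs). A call is *position-specific* when the same destination
residue leaves the intensity above the threshold at every other position,
the pattern seen for the critical W→N mutation of the CD44v6-inhibiting
parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import AA_INDEX, AMINO_ACIDS
from .library_design import PeptideEntry


@dataclass
class SubstitutionMatrix:
    parent: str
    parent_id: str
    matrix: np.ndarray  # (len(parent), 20) Int. values; NaN where masked
    mask: np.ndarray  # True where no measurement exists

    def __post_init__(self) -> None:
        expected = (len(self.parent), len(AMINO_ACIDS))
        if self.matrix.shape != expected or self.mask.shape != expected:
            raise ValueError(f"matrix/mask must have shape {expected}")

    def value(self, pos: int, residue: str) -> float:
        """Int. at 1-based position *pos* for destination *residue*."""
        return float(self.matrix[pos - 1, AA_INDEX[residue]])


def build_substitution_matrix(
    parent_id: str,
    library: Sequence[PeptideEntry],
    measurements: Mapping[str, float],
) -> SubstitutionMatrix:
    """Place each variant's Int. at (sub_pos, sub_to); missing variants are
    masked, never imputed.

    Measurements whose ids belong to this parent's variant namespace but
    match no library entry raise, so a value can never enter the matrix
    without library provenance.
    """
    variants = [
        e
        for e in library
        if e.group == "substitution" and e.peptide_id.startswith(f"{parent_id}_")
    ]
    if not variants:
        raise ValueError(f"library contains no substitution entries for parent {parent_id!r}")
    parent_seq = variants[0].parent
    if parent_seq is None:
        raise ValueError(f"substitution entries for {parent_id!r} lack a parent sequence")
    L = len(parent_seq)
    matrix = np.full((L, len(AMINO_ACIDS)), np.nan)
    mask = np.ones((L, len(AMINO_ACIDS)), dtype=bool)
    known_ids = set()
    parent_int: float | None = None
    for e in variants:
        known_ids.add(e.peptide_id)
        if e.sub_pos is None:  # the parent's own entry
            if e.sequence != parent_seq:
                raise ValueError(f"parent entry {e.peptide_id!r} does not match {parent_seq!r}")
            if e.peptide_id in measurements:
                parent_int = float(measurements[e.peptide_id])
            continue
        if e.sub_from != parent_seq[e.sub_pos - 1]:
            raise ValueError(
                f"variant {e.peptide_id!r}: sub_from {e.sub_from!r} does not match "
                f"parent residue {parent_seq[e.sub_pos - 1]!r} at position {e.sub_pos}"
            )
        if e.peptide_id in measurements:
            matrix[e.sub_pos - 1, AA_INDEX[e.sub_to]] = float(measurements[e.peptide_id])
            mask[e.sub_pos - 1, AA_INDEX[e.sub_to]] = False
    stray = [
        mid
        for mid in measurements
        if mid.startswith(f"{parent_id}_s") and mid not in known_ids
    ]
    if stray:
        raise ValueError(
            f"measured variants absent from library metadata for {parent_id!r}: {stray[:5]}"
        )
    if parent_int is not None:
        for pos0, aa in enumerate(parent_seq):
            matrix[pos0, AA_INDEX[aa]] = parent_int
            mask[pos0, AA_INDEX[aa]] = False
    return SubstitutionMatrix(parent=parent_seq, parent_id=parent_id, matrix=matrix, mask=mask)


@dataclass(frozen=True)
class CriticalSubstitution:
    pos: int  # 1-based
    residue: str
    intensity: float
    specific: bool  # True when the residue is benign at every other position


def find_critical_substitutions(
    matrix: SubstitutionMatrix, threshold: float, position_specific: bool = True
) -> list[CriticalSubstitution]:
    """Cells with Int. at or below *threshold*, sorted by intensity.

    Diagonal (parent-residue) cells are not substitutions and are never
    called. With *position_specific*, each call is flagged specific when
    every other position's cell for the same destination residue is
    unmasked-and-above threshold or masked.
    """
    calls: list[CriticalSubstitution] = []
    L = len(matrix.parent)
    for pos0 in range(L):
        for aa, j in AA_INDEX.items():
            if matrix.mask[pos0, j] or aa == matrix.parent[pos0]:
                continue
            value = float(matrix.matrix[pos0, j])
            if value <= threshold:
                specific = True
                if position_specific:
                    for other0 in range(L):
                        if other0 == pos0 or matrix.parent[other0] == aa:
                            continue
                        if not matrix.mask[other0, j] and matrix.matrix[other0, j] <= threshold:
                            specific = False
                            break
                calls.append(
                    CriticalSubstitution(pos=pos0 + 1, residue=aa, intensity=value, specific=specific)
                )
    calls.sort(key=lambda c: (c.intensity, c.pos, c.residue))
    return calls
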