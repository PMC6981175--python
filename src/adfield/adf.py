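"""Assemblage dispersion-field algebra.

The occurrence of S species over N grid cells is summarised in a binary
presence-absence matrix P (species x cells).  Row sums are species range
sizes r_i, column sums are cell richness s_j.  The dispersion-field matrix

    D = P' P

is the symmetric site-by-site matrix whose entry D[j, k] counts the species
shared by cells j and k; row j of D is the assemblage dispersion field
(ADF) of focal cell j.  The row sum of D at j equals the dispersion-field
volume sum_i p_ij * r_i — the summed range sizes of the species present in
j — and dividing by s_j gives the mean cosmopolitanism (mean range size of
the locally present species).

P and D are held sparse; per-cell fields are computed without materialising
the full N x N product, so the algebra scales past the ~1700-cell domains
it was designed around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .errors import ValidationError


@dataclass(eq=False)
class PresenceAbsence:
    """Binary species-by-cell incidence matrix with labels.

    ``matrix`` is an ``(S, N)`` sparse CSR matrix of 0/1 indicators.
    ``species`` are row labels, ``cell_ids`` column labels (aligned with a
    :class:`~adfield.domain.GridDomain` when used together).
    """

    matrix: sparse.csr_matrix
    species: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        m = sparse.csr_matrix(self.matrix, dtype=np.int64)
        m.eliminate_zeros()
        if m.nnz and not np.all(m.data == 1):
            raise ValidationError("presence-absence entries must be 0 or 1")
        self.matrix = m
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.species = list(self.species)
        s, n = m.shape
        if len(self.species) != s or len(self.cell_ids) != n:
            raise ValidationError("label lengths disagree with matrix shape")
        if s == 0 or n == 0:
            raise ValidationError("presence-absence matrix must be non-empty")
        if np.any(self.range_sizes < 1):
            empty = [self.species[i] for i in np.flatnonzero(self.range_sizes < 1)]
            raise ValidationError(f"species with empty ranges: {empty}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dense(
        cls, array: np.ndarray, species: Sequence[str] | None = None,
        cell_ids: Sequence[int] | None = None,
    ) -> "PresenceAbsence":
        array = np.asarray(array)
        s, n = array.shape
        return cls(
            sparse.csr_matrix(array),
            species=list(species) if species is not None else [f"sp{i}" for i in range(s)],
            cell_ids=np.asarray(cell_ids if cell_ids is not None else np.arange(n)),
        )

    @classmethod
    def from_ranges(
        cls,
        ranges: Sequence[np.ndarray],
        n_cells: int,
        species: Sequence[str] | None = None,
        cell_ids: Sequence[int] | None = None,
    ) -> "PresenceAbsence":
        """Stack per-species occupied-cell index arrays into a matrix."""
        rows, cols = [], []
        for i, cells in enumerate(ranges):
            cells = np.asarray(cells, dtype=np.int64)
            rows.append(np.full(len(cells), i, dtype=np.int64))
            cols.append(cells)
        m = sparse.csr_matrix(
            (
                np.ones(sum(len(c) for c in cols), dtype=np.int64),
                (np.concatenate(rows), np.concatenate(cols)),
            ),
            shape=(len(ranges), n_cells),
        )
        return cls(
            m,
            species=list(species) if species is not None else [f"sp{i}" for i in range(len(ranges))],
            cell_ids=np.asarray(cell_ids if cell_ids is not None else np.arange(n_cells)),
        )

    # -- marginals --------------------------------------------------------

    @property
    def n_species(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def range_sizes(self) -> np.ndarray:
        """r_i: number of cells occupied by each species (row sums)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @property
    def richness(self) -> np.ndarray:
        """s_j: number of species present in each cell (column sums)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def cell_index(self, cell_id: int) -> int:
        hits = np.flatnonzero(self.cell_ids == int(cell_id))
        if len(hits) != 1:
            raise ValidationError(f"unknown cell id {cell_id!r}")
        return int(hits[0])

    def species_in_cell(self, j: int) -> np.ndarray:
        """Row indices of the species present in internal cell index j."""
        return self.matrix.getcol(j).tocoo().row


@dataclass
class DispersionField:
    """One row of D: shared-species counts of a focal cell with all cells."""

    focal: int  # internal cell index
    counts: np.ndarray
    richness: int
    empty: bool = field(default=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.richness > 0 and self.counts[self.focal] != self.richness:
            raise ValidationError("field value at the focal cell must equal richness")


def adf_matrix(P: PresenceAbsence) -> sparse.csr_matrix:
    """The full dispersion-field matrix D = P' P (sparse, N x N).

    D is symmetric with diagonal equal to cell richness; D[j, k] is the
    number of species occurring in both cells j and k.
    """
    D = (P.matrix.T @ P.matrix).tocsr()
    D.sum_duplicates()
    return D


def dispersion_field(P: PresenceAbsence, j: int) -> DispersionField:
    """Row j of D for internal cell index ``j``, without materialising D.

    Cells with zero richness yield an all-zero field with the ``empty``
    flag set and a warning, rather than an error: empty land cells are a
    legitimate part of a lattice.
    """
    n = P.n_cells
    if not 0 <= j < n:
        raise ValidationError(f"cell index {j} out of range for N={n}")
    present = P.species_in_cell(j)
    if len(present) == 0:
        warnings.warn(f"cell index {j} has zero richness; returning an empty field")
        return DispersionField(focal=j, counts=np.zeros(n, dtype=np.int64),
                               richness=0, empty=True)
    counts = np.asarray(P.matrix[present].sum(axis=0)).ravel()
    return DispersionField(focal=j, counts=counts, richness=len(present))


def df_volume(P: PresenceAbsence, j: int) -> int:
    """Dispersion-field volume of cell j: sum of r_i over species present."""
    if not 0 <= j < P.n_cells:
        raise ValidationError(f"cell index {j} out of range for N={P.n_cells}")
    present = P.species_in_cell(j)
    return int(P.range_sizes[present].sum())


def mean_cosmopolitanism(P: PresenceAbsence, j: int) -> float:
    """Mean range size of the species present in cell j (volume / richness)."""
    s_j = int(P.richness[j])
    if s_j == 0:
        raise ValidationError(
            f"mean cosmopolitanism undefined for empty cell index {j}"
        )
    return df_volume(P, j) / s_j
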