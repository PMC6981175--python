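"""Lattice domain of land grid cells.

A :class:`GridDomain` is the geometric substrate for everything else in the
package: an ordered collection of land cells on a regular lattice, each with
a geographic center (x = longitude, y = latitude, decimal degrees), an
integer lattice position, and optional per-cell layers (ecoregion label,
available energy, elevation).  Adjacency between cells is rook (4-neighbor)
by default or queen (8-neighbor), derived from lattice positions.

Cell centers follow the convention that a 1-degree cell spanning
``[lon, lon+1) x [lat, lat+1)`` has its center at ``(lon+0.5, lat+0.5)``;
all centroid arithmetic in the package operates on these raw coordinates
without any cos-latitude area weighting, and boundary distances are graph
steps on the lattice, not kilometres.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ROOK_OFFSETS: tuple[tuple[int, int], ...] = ((1, 0), (-1, 0), (0, 1), (0, -1))
QUEEN_OFFSETS: tuple[tuple[int, int], ...] = ROOK_OFFSETS + (
    (1, 1),
    (1, -1),
    (-1, 1),
    (-1, -1),
)

#: Recognised adjacency modes and their lattice offsets.
ADJACENCY_OFFSETS: Mapping[str, tuple[tuple[int, int], ...]] = {
    "rook": ROOK_OFFSETS,
    "queen": QUEEN_OFFSETS,
}


@dataclass(eq=False)
class GridDomain:
    """The lattice of land cells with coordinates and optional layers.

    Parameters
    ----------
    centers
        ``(N, 2)`` float array of cell centers, columns ``(x, y)``.
    lattice
        ``(N, 2)`` int array of lattice positions ``(ix, iy)``; distinct per
        cell.  Adjacency is computed from these.
    cell_ids
        ``(N,)`` int array of external cell identifiers (need not be
        contiguous; synthetic domains use ``0..N-1``).
    adjacency_mode
        ``"rook"`` (default) or ``"queen"``.
    ecoregion, energy, elevation_m
        Optional ``(N,)`` per-cell layers.
    """

    centers: np.ndarray
    lattice: np.ndarray
    cell_ids: np.ndarray
    adjacency_mode: str = "rook"
    ecoregion: np.ndarray | None = None
    energy: np.ndarray | None = None
    elevation_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.lattice = np.asarray(self.lattice, dtype=np.int64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValidationError("centers must be an (N, 2) array")
        n = len(self.centers)
        if self.lattice.shape != (n, 2) or self.cell_ids.shape != (n,):
            raise ValidationError("centers, lattice and cell_ids disagree in length")
        if self.adjacency_mode not in ADJACENCY_OFFSETS:
            raise ValidationError(
                f"unknown adjacency mode {self.adjacency_mode!r}; "
                f"expected one of {sorted(ADJACENCY_OFFSETS)}"
            )
        if n == 0:
            raise ValidationError("domain must contain at least one cell")
        if len(np.unique(self.cell_ids)) != n:
            raise ValidationError("cell_ids must be unique")
        pos = {tuple(p) for p in self.lattice}
        if len(pos) != n:
            seen: dict[tuple[int, int], int] = {}
            dups = []
            for cid, p in zip(self.cell_ids, map(tuple, self.lattice)):
                if p in seen:
                    dups.append((seen[p], int(cid)))
                else:
                    seen[p] = int(cid)
            raise ValidationError(f"duplicate lattice positions for cells: {dups}")
        for layer in (self.ecoregion, self.energy, self.elevation_m):
            if layer is not None and np.asarray(layer).shape != (n,):
                raise ValidationError("per-cell layers must have shape (N,)")
        if self.ecoregion is not None:
            self.ecoregion = np.asarray(self.ecoregion, dtype=np.int64)
        if self.energy is not None:
            self.energy = np.asarray(self.energy, dtype=float)
            if np.any(self.energy < 0):
                raise ValidationError("energy layer must be nonnegative")
        if self.elevation_m is not None:
            self.elevation_m = np.asarray(self.elevation_m, dtype=float)

    # -- indexing ---------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @cached_property
    def _id_to_index(self) -> dict[int, int]:
        return {int(c): i for i, c in enumerate(self.cell_ids)}

    @cached_property
    def _pos_to_index(self) -> dict[tuple[int, int], int]:
        return {(int(x), int(y)): i for i, (x, y) in enumerate(self.lattice)}

    def index_of(self, cell_id: int) -> int:
        """Internal array index of an external cell id."""
        try:
            return self._id_to_index[int(cell_id)]
        except KeyError:
            raise ValidationError(f"unknown cell id {cell_id!r}") from None

    # -- adjacency --------------------------------------------------------

    @cached_property
    def neighbor_lists(self) -> tuple[np.ndarray, ...]:
        """Per-cell arrays of neighbouring internal indices (land cells only)."""
        offsets = ADJACENCY_OFFSETS[self.adjacency_mode]
        pos = self._pos_to_index
        out = []
        for ix, iy in self.lattice:
            nbrs = [
                pos[(int(ix) + dx, int(iy) + dy)]
                for dx, dy in offsets
                if (int(ix) + dx, int(iy) + dy) in pos
            ]
            out.append(np.array(sorted(nbrs), dtype=np.int64))
        return tuple(out)


@dataclass
class BoundaryDistanceMap:
    """Graph-step distance of each cell of one ecoregion to its boundary.

    ``distance`` is an ``(N,)`` float array aligned with the domain; cells
    outside the region hold ``nan``.  Distance 0 means the cell touches the
    region boundary: it has a lattice neighbour in a different ecoregion or
    a lattice neighbour position outside the domain.
    """

    region_label: int
    distance: np.ndarray
    cells: np.ndarray = field(repr=False)  # internal indices of the region

    def value(self, domain: GridDomain, cell_id: int) -> float:
        return float(self.distance[domain.index_of(cell_id)])


def build_domain(
    grid_table: pd.DataFrame,
    adjacency_mode: str = "rook",
    cell_size: float = 1.0,
) -> GridDomain:
    """Build a :class:`GridDomain` from a grid-cell table.

    The table needs columns ``cell_id``, ``lon``, ``lat`` (cell-center
    decimal degrees) and may carry ``ecoregion``, ``energy`` and
    ``elevation_m``.  Lattice positions are recovered by dividing the
    coordinates by ``cell_size``; centers must sit on a regular lattice.
    """
    required = {"cell_id", "lon", "lat"}
    missing = required - set(grid_table.columns)
    if missing:
        raise ValidationError(f"grid table missing columns: {sorted(missing)}")
    lon = pd.to_numeric(grid_table["lon"], errors="coerce").to_numpy(dtype=float)
    lat = pd.to_numeric(grid_table["lat"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        bad = grid_table.loc[~np.isfinite(lon) | ~np.isfinite(lat), "cell_id"]
        raise ValidationError(f"non-numeric coordinates for cells: {list(bad)}")
    if cell_size <= 0:
        raise ValidationError("cell_size must be positive")

    rel_x = (lon - lon.min()) / cell_size
    rel_y = (lat - lat.min()) / cell_size
    ix = np.rint(rel_x).astype(np.int64)
    iy = np.rint(rel_y).astype(np.int64)
    if np.any(np.abs(rel_x - ix) > 0.25) or np.any(np.abs(rel_y - iy) > 0.25):
        raise ValidationError(
            "cell centers do not sit on a regular lattice of the given cell_size"
        )
    lattice = np.column_stack([ix, iy])

    def _layer(name):
        if name in grid_table.columns:
            return grid_table[name].to_numpy()
        return None

    return GridDomain(
        centers=np.column_stack([lon, lat]),
        lattice=lattice,
        cell_ids=grid_table["cell_id"].to_numpy(dtype=np.int64),
        adjacency_mode=adjacency_mode,
        ecoregion=_layer("ecoregion"),
        energy=_layer("energy"),
        elevation_m=_layer("elevation_m"),
    )


def neighbors(domain: GridDomain, cell_id: int) -> set[int]:
    """External ids of the land cells adjacent to ``cell_id``."""
    idx = domain.index_of(cell_id)
    return {int(domain.cell_ids[k]) for k in domain.neighbor_lists[idx]}


def domain_centroid(domain: GridDomain) -> tuple[float, float]:
    """Unweighted mean of the land-cell centers."""
    c = domain.centers.mean(axis=0)
    return float(c[0]), float(c[1])


def boundary_distance(domain: GridDomain, region_label: int) -> BoundaryDistanceMap:
    """Multi-source BFS distance (graph steps) to the region's boundary.

    A cell is a boundary cell (distance 0) iff one of its lattice-offset
    neighbours lies in a different ecoregion or outside the domain.  The
    BFS is restricted to cells of the region and uses the domain's
    adjacency mode.
    """
    if domain.ecoregion is None:
        raise ValidationError("domain has no ecoregion layer")
    in_region = domain.ecoregion == region_label
    if not in_region.any():
        raise ValidationError(f"ecoregion label {region_label!r} absent from domain")

    offsets = ADJACENCY_OFFSETS[domain.adjacency_mode]
    pos = domain._pos_to_index
    dist = np.full(domain.n_cells, np.nan)
    queue: deque[int] = deque()
    for i in np.flatnonzero(in_region):
        ix, iy = (int(v) for v in domain.lattice[i])
        for dx, dy in offsets:
            j = pos.get((ix + dx, iy + dy))
            if j is None or not in_region[j]:
                dist[i] = 0.0
                queue.append(i)
                break
    nbr = domain.neighbor_lists
    while queue:
        i = queue.popleft()
        for j in nbr[i]:
            if in_region[j] and np.isnan(dist[j]):
                dist[j] = dist[i] + 1
                queue.append(int(j))
    return BoundaryDistanceMap(
        region_label=int(region_label),
        distance=dist,
        cells=np.flatnonzero(in_region),
    )


def is_connected(domain: GridDomain, cells: Iterable[int] | Sequence[int]) -> bool:
    """Whether a set of internal cell indices forms one adjacency component."""
    cells = set(int(c) for c in cells)
    if not cells:
        return True
    start = next(iter(cells))
    seen = {start}
    stack = [start]
    nbr = domain.neighbor_lists
    while stack:
        i = stack.pop()
        for j in nbr[i]:
            j = int(j)
            if j in cells and j not in seen:
                seen.add(j)
                stack.append(j)
    return seen == cells
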