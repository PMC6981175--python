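"""ADF trimming, centers of gravity, and asymmetry-vector diagrams.

The asymmetry of a dispersion field is summarised by a vector from the
focal cell's center to the center of gravity of the field.  Two centers
are exposed:

* the *range-centroid* center of gravity of the untrimmed field — the mean
  of the range centroids (x̄_i, ȳ_i) of the species present in the focal
  cell; and
* the *trimmed-mass* center — the shared-species-count-weighted centroid
  of the central region that survives trimming at a cutoff c.

Trimming removes cells that share only a small fraction of the focal
assemblage: under the default convention a cell k is retained iff
D[j, k] / s_j >= c, so the focal cell (sharing all s_j species with
itself) is always retained and the scale is comparable across taxa with
different richness.  An alternative normalisation by the maximum
off-focal shared count is available via ``cutoff_mode="max_offfocal"``.

Vector lengths are in coordinate degrees; angles, where needed, are
measured counter-clockwise from east.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .adf import DispersionField, PresenceAbsence, dispersion_field
from .domain import GridDomain
from .errors import ValidationError

CutoffMode = Literal["focal_richness", "max_offfocal"]
WeightMode = Literal["counts", "uniform"]

#: Number of equal-width bins used for vector-length histograms.
HISTOGRAM_BINS = 30


def species_centroids(P: PresenceAbsence, domain: GridDomain) -> np.ndarray:
    """(S, 2) array of per-species range centroids (x̄_i, ȳ_i).

    The centroid of species i is the unweighted mean of the centers of its
    occupied cells: (1/r_i) * sum_j p_ij (x_j, y_j).
    """
    if P.n_cells != domain.n_cells:
        raise ValidationError("presence-absence and domain disagree on N")
    sums = P.matrix @ domain.centers
    return sums / P.range_sizes[:, None]


def species_centroid(P: PresenceAbsence, domain: GridDomain, i: int) -> tuple[float, float]:
    """Range centroid of species row i."""
    if not 0 <= i < P.n_species:
        raise ValidationError(f"species index {i} out of range")
    c = species_centroids(P, domain)[i]
    return float(c[0]), float(c[1])


def untrimmed_center_of_gravity(
    P: PresenceAbsence, domain: GridDomain, j: int
) -> tuple[float, float]:
    """Center of gravity of the full ADF of cell j.

    Defined as the mean of the range centroids of the species present in
    j: (1/s_j) * sum_i p_ij (x̄_i, ȳ_i).  Undefined (raises) for empty
    cells.
    """
    present = P.species_in_cell(j)
    if len(present) == 0:
        raise ValidationError(f"center of gravity undefined: cell index {j} is empty")
    c = species_centroids(P, domain)[present].mean(axis=0)
    return float(c[0]), float(c[1])


@dataclass
class CentralRegion:
    """Cells of a dispersion field surviving trimming at a cutoff."""

    focal: int
    cutoff: float
    cells: np.ndarray  # internal indices, focal included
    counts: np.ndarray  # shared-species counts of the retained cells


@dataclass
class AsymmetryVector:
    """Vector from a focal cell's center to its field's center of gravity."""

    focal: int
    focal_center: tuple[float, float]
    center_of_gravity: tuple[float, float]
    dx: float
    dy: float
    degenerate: bool = field(default=False)

    @property
    def length(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    @property
    def angle_deg(self) -> float:
        """Direction counter-clockwise from east, in degrees."""
        return float(np.degrees(np.arctan2(self.dy, self.dx)))


def trim_adf(
    f: DispersionField,
    cutoff: float,
    cutoff_mode: CutoffMode = "focal_richness",
) -> CentralRegion:
    """Central region of a dispersion field at trimming cutoff c.

    ``focal_richness`` (default): retain cells sharing at least ``c * s_j``
    species with the focal cell.  ``max_offfocal``: threshold against the
    maximum off-focal shared count instead.  The focal cell is always
    retained.
    """
    if not 0 < cutoff <= 1:
        raise ValidationError(f"cutoff must be in (0, 1], got {cutoff}")
    if f.richness == 0:
        raise ValidationError("cannot trim the field of an empty cell")
    if cutoff_mode == "focal_richness":
        ref = f.richness
    elif cutoff_mode == "max_offfocal":
        off = np.delete(f.counts, f.focal)
        ref = off.max() if len(off) else 0
    else:
        raise ValidationError(f"unknown cutoff mode {cutoff_mode!r}")
    keep = f.counts >= cutoff * ref
    keep &= f.counts > 0
    keep[f.focal] = True
    cells = np.flatnonzero(keep)
    return CentralRegion(
        focal=f.focal, cutoff=float(cutoff), cells=cells,
        counts=f.counts[cells],
    )


def region_center_of_gravity(
    region: CentralRegion,
    domain: GridDomain,
    weights: WeightMode = "counts",
) -> tuple[float, float]:
    """Centroid of a central region, weighted by shared counts (default)."""
    if weights == "counts":
        w = region.counts.astype(float)
    elif weights == "uniform":
        w = np.ones(len(region.cells))
    else:
        raise ValidationError(f"unknown weight mode {weights!r}")
    c = (w[:, None] * domain.centers[region.cells]).sum(axis=0) / w.sum()
    return float(c[0]), float(c[1])


def asymmetry_vector(
    f: DispersionField,
    domain: GridDomain,
    cutoff: float,
    cutoff_mode: CutoffMode = "focal_richness",
    weights: WeightMode = "counts",
    center: Literal["trimmed_mass", "range_centroids"] = "trimmed_mass",
    P: PresenceAbsence | None = None,
) -> AsymmetryVector:
    """Asymmetry vector of a focal cell's dispersion field.

    With ``center="trimmed_mass"`` (default) the head of the vector is the
    weighted centroid of the trimmed central region; with
    ``center="range_centroids"`` it is the untrimmed mean-of-range-centroids
    center (requires ``P``).  A region degenerate to the focal cell alone
    yields a zero vector with the ``degenerate`` flag set.
    """
    focal_center = domain.centers[f.focal]
    if center == "range_centroids":
        if P is None:
            raise ValidationError("center='range_centroids' requires P")
        cog = untrimmed_center_of_gravity(P, domain, f.focal)
        degenerate = False
    else:
        region = trim_adf(f, cutoff, cutoff_mode)
        degenerate = len(region.cells) == 1
        cog = region_center_of_gravity(region, domain, weights)
    dx = cog[0] - float(focal_center[0])
    dy = cog[1] - float(focal_center[1])
    return AsymmetryVector(
        focal=f.focal,
        focal_center=(float(focal_center[0]), float(focal_center[1])),
        center_of_gravity=cog,
        dx=dx,
        dy=dy,
        degenerate=degenerate,
    )


@dataclass
class SymmetryDiagram:
    """Per-cell asymmetry vectors for a whole domain, plus summaries."""

    table: pd.DataFrame  # cell_id, lon, lat, dx, dy, length, richness, cutoff
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    metadata: dict

    @property
    def lengths(self) -> np.ndarray:
        return self.table["length"].to_numpy()


def symmetry_diagram(
    P: PresenceAbsence,
    domain: GridDomain,
    cutoff: float,
    cutoff_mode: CutoffMode = "focal_richness",
    weights: WeightMode = "counts",
    center: Literal["trimmed_mass", "range_centroids"] = "trimmed_mass",
) -> SymmetryDiagram:
    """Asymmetry vectors for every non-empty cell of the domain.

    The vector-length histogram uses ``HISTOGRAM_BINS`` equal-width bins
    over [0, max length]; binning is recorded in the metadata.
    """
    if P.n_cells != domain.n_cells:
        raise ValidationError("presence-absence and domain disagree on N")
    rows = []
    richness = P.richness
    for j in range(P.n_cells):
        if richness[j] == 0:
            continue
        f = dispersion_field(P, j)
        v = asymmetry_vector(
            f, domain, cutoff, cutoff_mode=cutoff_mode, weights=weights,
            center=center, P=P,
        )
        rows.append(
            {
                "cell_id": int(domain.cell_ids[j]),
                "lon": v.focal_center[0],
                "lat": v.focal_center[1],
                "dx": v.dx,
                "dy": v.dy,
                "length": v.length,
                "richness": int(richness[j]),
                "cutoff": float(cutoff),
            }
        )
    table = pd.DataFrame(rows)
    lengths = table["length"].to_numpy() if len(table) else np.array([0.0])
    top = float(lengths.max()) if lengths.max() > 0 else 1.0
    counts, edges = np.histogram(lengths, bins=HISTOGRAM_BINS, range=(0.0, top))
    return SymmetryDiagram(
        table=table,
        histogram_counts=counts,
        histogram_edges=edges,
        metadata={
            "cutoff": float(cutoff),
            "cutoff_mode": cutoff_mode,
            "weights": weights,
            "center": center,
            "histogram_bins": HISTOGRAM_BINS,
            "histogram_range": [0.0, top],
        },
    )
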