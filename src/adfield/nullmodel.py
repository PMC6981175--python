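"""Spreading-dye null ensembles and standardized effect sizes.

The null model asks: how asymmetric would a cell's dispersion field be if
every species present there had a randomly placed cohesive range of the
same size?  Concretely:

1. A *sampling population* of spreading-dye ranges is pre-generated for
   every needed range size, drawing until every cell is intersected by at
   least ``coverage`` (default 100) stored ranges of each size.
2. A null dispersion field for focal cell j is assembled by drawing, for
   each species present in j, one stored range of that species' empirical
   size from among the stored ranges intersecting j — so the cell's
   empirical range-size frequency distribution is preserved exactly — and
   overlaying the draws.
3. Repeating R times (default 1000) and pushing each null field through
   the same trimming and asymmetry-vector pipeline as the empirical data
   yields the null distribution λ of symmetry values, and the deviation of
   the empirical value ν is summarised as the standardized effect size

       SES = (ν − μ(λ)) / σ(λ),

   with σ the sample (n−1) standard deviation.

Size-1 ranges need no population: the only size-1 range intersecting j is
{j} itself.  Draws are with replacement from the per-(cell, size) index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .adf import DispersionField, PresenceAbsence, dispersion_field
from .domain import GridDomain
from .dye import null_range
from .errors import InfeasibleSimulationError, ValidationError
from .symmetry import CutoffMode, WeightMode, asymmetry_vector

#: Minimum stored ranges of each size intersecting every cell.
DEFAULT_COVERAGE = 100
#: Null-ensemble replicates behind each SES value.
DEFAULT_REPLICATES = 1000


def _domain_hash(domain: GridDomain) -> str:
    h = hashlib.sha256()
    h.update(domain.lattice.tobytes())
    h.update(domain.adjacency_mode.encode())
    return h.hexdigest()[:16]


@dataclass(eq=False)
class SamplingPopulation:
    """Stored spreading-dye ranges, indexed by (cell, size)."""

    domain: GridDomain
    ranges: dict[int, list[np.ndarray]]  # size -> list of sorted index arrays
    coverage: int
    seed: int | None = None
    index: dict[int, list[np.ndarray]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {
                s: _build_cell_index(rs, self.domain.n_cells)
                for s, rs in self.ranges.items()
            }

    @property
    def sizes(self) -> list[int]:
        return sorted(self.ranges)

    def intersecting(self, size: int, j: int) -> np.ndarray:
        """Ids (into ``ranges[size]``) of stored ranges covering cell j."""
        if size not in self.index:
            raise ValidationError(f"no sampling population for range size {size}")
        return self.index[size][j]


def _build_cell_index(ranges: list[np.ndarray], n_cells: int) -> list[np.ndarray]:
    buckets: list[list[int]] = [[] for _ in range(n_cells)]
    for rid, cells in enumerate(ranges):
        for c in cells:
            buckets[int(c)].append(rid)
    return [np.asarray(b, dtype=np.int64) for b in buckets]


def build_population(
    domain: GridDomain,
    sizes: Sequence[int],
    coverage: int = DEFAULT_COVERAGE,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SamplingPopulation:
    """Generate null ranges per size until per-cell coverage is reached.

    For each requested size, draws spreading-dye ranges until every cell is
    intersected by at least ``coverage`` of them.  Size 1 entries are
    skipped (handled analytically downstream).  A disconnected domain that
    can never be covered raises, naming the uncovered cells.
    """
    if coverage < 1:
        raise ValidationError("coverage must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = domain.n_cells
    wanted = sorted({int(s) for s in sizes if int(s) != 1})
    if any(s < 1 or s > n for s in wanted):
        raise ValidationError(f"range sizes must lie in 1..{n}")

    ranges: dict[int, list[np.ndarray]] = {}
    for size in wanted:
        stored: list[np.ndarray] = []
        counts = np.zeros(n, dtype=np.int64)
        # generous cap; only a disconnected domain should ever hit it
        cap = max(200, 60 * int(np.ceil(coverage * n / size)))
        while counts.min() < coverage:
            if len(stored) >= cap:
                uncovered = [int(domain.cell_ids[c])
                             for c in np.flatnonzero(counts < coverage)]
                raise InfeasibleSimulationError(
                    f"coverage {coverage} unreachable for size {size}; "
                    f"uncovered cells {uncovered[:20]}",
                    cells=uncovered,
                )
            r = null_range(domain, size, rng)
            stored.append(r.cells)
            counts[r.cells] += 1
        ranges[size] = stored
    return SamplingPopulation(domain=domain, ranges=ranges, coverage=coverage, seed=seed)


def null_adf(
    pop: SamplingPopulation,
    j: int,
    sizes_in_cell: Sequence[int],
    rng: np.random.Generator,
) -> DispersionField:
    """One null dispersion field for focal cell j.

    Draws, for each size in the cell's empirical range-size multiset, one
    stored range of that size intersecting j (uniformly, with replacement)
    and overlays the draws into shared-species counts.  Every drawn range
    contains j, so the field value at j equals the number of species.
    """
    n = pop.domain.n_cells
    if not 0 <= j < n:
        raise ValidationError(f"cell index {j} out of range")
    sizes = [int(s) for s in sizes_in_cell]
    if not sizes:
        raise ValidationError("sizes_in_cell must be non-empty")
    counts = np.zeros(n, dtype=np.int64)
    for s in sizes:
        if s == 1:
            counts[j] += 1
            continue
        ids = pop.intersecting(s, j)
        if len(ids) == 0:
            raise InfeasibleSimulationError(
                f"no stored range of size {s} intersects cell index {j}; "
                "rebuild the population with higher coverage",
                cells=[j],
            )
        counts[pop.ranges[s][int(ids[rng.integers(len(ids))])]] += 1
    return DispersionField(focal=j, counts=counts, richness=len(sizes))


@dataclass
class NullEnsemble:
    """Null distribution of symmetry values for one focal cell."""

    focal: int
    lam: np.ndarray  # R simulated vector lengths
    nu: float | None = None  # empirical vector length

    @property
    def R(self) -> int:
        return len(self.lam)

    @property
    def mu(self) -> float:
        return float(np.mean(self.lam))

    @property
    def sigma(self) -> float:
        return float(np.std(self.lam, ddof=1))


def null_symmetry_distribution(
    pop: SamplingPopulation,
    domain: GridDomain,
    j: int,
    sizes_in_cell: Sequence[int],
    cutoff: float,
    R: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    nu: float | None = None,
    cutoff_mode: CutoffMode = "focal_richness",
    weights: WeightMode = "counts",
    trimmed: bool = True,
) -> NullEnsemble:
    """R independent null symmetry (vector-length) values for cell j.

    Each replicate draws a fresh null ADF and runs it through the same
    trimming and asymmetry-vector computation as the empirical pipeline
    (``trimmed=False`` measures the untrimmed count-weighted vector
    instead, for sensitivity analyses).
    """
    if R < 2:
        raise ValidationError("R must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    lam = np.empty(R)
    eff_cutoff = cutoff if trimmed else 1e-12
    for r in range(R):
        f = null_adf(pop, j, sizes_in_cell, rng)
        v = asymmetry_vector(f, domain, eff_cutoff, cutoff_mode=cutoff_mode,
                             weights=weights)
        lam[r] = v.length
    return NullEnsemble(focal=j, lam=lam, nu=nu)


def ses(ensemble: NullEnsemble) -> float:
    """Standardized effect size (ν − μ(λ)) / σ(λ).

    Returns ``nan`` when σ(λ) = 0 (a degenerate null); the raw deviation
    ν − μ stays available on the ensemble.  Raises on an empty λ or a
    missing empirical value.
    """
    if ensemble.R == 0:
        raise ValidationError("empty null ensemble")
    if ensemble.nu is None:
        raise ValidationError("ensemble has no empirical value ν")
    sigma = ensemble.sigma
    if sigma == 0:
        return float("nan")
    return (ensemble.nu - ensemble.mu) / sigma


@dataclass
class SESMap:
    """Per-cell SES of empirical asymmetry against cell-specific nulls."""

    table: pd.DataFrame  # cell_id, nu, mu, sigma, ses, R, cutoff, flag
    cutoff: float
    R: int

    @property
    def values(self) -> np.ndarray:
        return self.table["ses"].to_numpy()


def ses_map(
    P: PresenceAbsence,
    domain: GridDomain,
    pop: SamplingPopulation,
    cutoff: float,
    R: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    cutoff_mode: CutoffMode = "focal_richness",
    weights: WeightMode = "counts",
    trimmed: bool = True,
) -> SESMap:
    """SES of every non-empty cell's asymmetry-vector length.

    Per-cell failures (e.g., a range size the population does not cover)
    are recorded in the ``flag`` column instead of aborting the whole map.
    """
    if rng is None:
        rng = np.random.default_rng()
    richness = P.richness
    r_i = P.range_sizes
    eff_cutoff = cutoff if trimmed else 1e-12
    rows = []
    for j in range(P.n_cells):
        if richness[j] == 0:
            continue
        f = dispersion_field(P, j)
        nu = asymmetry_vector(f, domain, eff_cutoff, cutoff_mode=cutoff_mode,
                              weights=weights).length
        sizes_in_cell = r_i[P.species_in_cell(j)]
        row = {"cell_id": int(domain.cell_ids[j]), "nu": nu, "R": R,
               "cutoff": float(cutoff)}
        try:
            ens = null_symmetry_distribution(
                pop, domain, j, sizes_in_cell, cutoff, R=R, rng=rng, nu=nu,
                cutoff_mode=cutoff_mode, weights=weights, trimmed=trimmed,
            )
            row["mu"] = ens.mu
            row["sigma"] = ens.sigma
            row["ses"] = ses(ens)
            row["flag"] = "zero_sigma" if ens.sigma == 0 else ""
        except InfeasibleSimulationError as exc:
            row.update(mu=np.nan, sigma=np.nan, ses=np.nan, flag=str(exc))
        rows.append(row)
    return SESMap(table=pd.DataFrame(rows), cutoff=float(cutoff), R=R)


# -- population persistence --------------------------------------------------


def save_population(pop: SamplingPopulation, directory: str | Path) -> None:
    """Persist a population as a JSON manifest plus per-size text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "domain_hash": _domain_hash(pop.domain),
        "sizes": pop.sizes,
        "coverage": pop.coverage,
        "seed": pop.seed,
        "n_cells": pop.domain.n_cells,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for size, stored in pop.ranges.items():
        with open(directory / f"ranges_{size}.txt", "w") as fh:
            for cells in stored:
                fh.write(" ".join(map(str, cells.tolist())) + "\n")


def load_population(directory: str | Path, domain: GridDomain) -> SamplingPopulation:
    """Load a persisted population, checking it matches the domain."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["domain_hash"] != _domain_hash(domain):
        raise ValidationError("population archive was built for a different domain")
    ranges: dict[int, list[np.ndarray]] = {}
    for size in manifest["sizes"]:
        stored = []
        with open(directory / f"ranges_{size}.txt") as fh:
            for line in fh:
                stored.append(np.array(line.split(), dtype=np.int64))
        ranges[int(size)] = stored
    return SamplingPopulation(
        domain=domain, ranges=ranges, coverage=int(manifest["coverage"]),
        seed=manifest.get("seed"),
    )
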