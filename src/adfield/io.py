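"""Interchange formats: grid tables, presence-absence matrices, outputs.

Grid tables are CSV with columns ``cell_id,lon,lat[,ecoregion][,energy]
[,elevation_m]``.  Presence-absence matrices round-trip through three
formats: wide CSV (rows = species, columns = cell ids), sparse triplet CSV
(``species,cell_id,value``), and MatrixMarket with sidecar label files
(``<prefix>.mtx``, ``<prefix>.species.txt``, ``<prefix>.cells.txt``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .adf import PresenceAbsence
from .domain import GridDomain, build_domain
from .errors import ValidationError
from .nullmodel import SESMap
from .symmetry import SymmetryDiagram


# -- grid tables -------------------------------------------------------------


def read_grid_csv(path: str | Path, adjacency_mode: str = "rook") -> GridDomain:
    return build_domain(pd.read_csv(path), adjacency_mode=adjacency_mode)


def write_grid_csv(domain: GridDomain, path: str | Path) -> None:
    table = pd.DataFrame(
        {"cell_id": domain.cell_ids, "lon": domain.centers[:, 0],
         "lat": domain.centers[:, 1]}
    )
    for name, layer in (("ecoregion", domain.ecoregion),
                        ("energy", domain.energy),
                        ("elevation_m", domain.elevation_m)):
        if layer is not None:
            table[name] = layer
    table.to_csv(path, index=False)


# -- presence-absence matrices ----------------------------------------------


def read_presence_csv(path: str | Path) -> PresenceAbsence:
    """Wide CSV: first column species labels, remaining columns cell ids."""
    df = pd.read_csv(path, index_col=0)
    return PresenceAbsence.from_dense(
        df.to_numpy(), species=[str(s) for s in df.index],
        cell_ids=[int(c) for c in df.columns],
    )


def write_presence_csv(P: PresenceAbsence, path: str | Path) -> None:
    pd.DataFrame(
        P.matrix.toarray(), index=P.species, columns=P.cell_ids
    ).to_csv(path)


def read_presence_triplets(path: str | Path) -> PresenceAbsence:
    """Sparse triplet CSV with columns ``species,cell_id,value``."""
    df = pd.read_csv(path)
    needed = {"species", "cell_id"}
    if not needed <= set(df.columns):
        raise ValidationError("triplet CSV needs 'species' and 'cell_id' columns")
    species = sorted(df["species"].astype(str).unique())
    cells = np.array(sorted(df["cell_id"].astype(int).unique()))
    srow = {s: i for i, s in enumerate(species)}
    ccol = {int(c): i for i, c in enumerate(cells)}
    rows = df["species"].astype(str).map(srow).to_numpy()
    cols = df["cell_id"].astype(int).map(ccol).to_numpy()
    m = sparse.csr_matrix(
        (np.ones(len(df), dtype=np.int64), (rows, cols)),
        shape=(len(species), len(cells)),
    )
    m.data[:] = 1  # collapse duplicate triplets
    return PresenceAbsence(m, species=species, cell_ids=cells)


def write_presence_triplets(P: PresenceAbsence, path: str | Path) -> None:
    coo = P.matrix.tocoo()
    pd.DataFrame(
        {"species": [P.species[i] for i in coo.row],
         "cell_id": P.cell_ids[coo.col], "value": coo.data}
    ).to_csv(path, index=False)


def write_presence_mtx(P: PresenceAbsence, prefix: str | Path) -> None:
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), P.matrix)
    prefix.with_suffix(".species.txt").write_text("\n".join(P.species) + "\n")
    prefix.with_suffix(".cells.txt").write_text(
        "\n".join(str(int(c)) for c in P.cell_ids) + "\n"
    )


def read_presence_mtx(prefix: str | Path) -> PresenceAbsence:
    prefix = Path(prefix)
    m = sparse.csr_matrix(spio.mmread(str(prefix.with_suffix(".mtx"))))
    species = prefix.with_suffix(".species.txt").read_text().splitlines()
    cells = np.array(
        [int(c) for c in prefix.with_suffix(".cells.txt").read_text().split()]
    )
    return PresenceAbsence(m, species=species, cell_ids=cells)


# -- analysis outputs --------------------------------------------------------


def write_symmetry_csv(diagram: SymmetryDiagram, path: str | Path) -> None:
    diagram.table.to_csv(path, index=False)


def symmetry_geojson(diagram: SymmetryDiagram) -> dict:
    """GeoJSON FeatureCollection of LineString arrows, for GIS rendering."""
    features = []
    for row in diagram.table.itertuples():
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [row.lon, row.lat],
                        [row.lon + row.dx, row.lat + row.dy],
                    ],
                },
                "properties": {
                    "cell_id": int(row.cell_id),
                    "length": row.length,
                    "richness": int(row.richness),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features,
            "metadata": diagram.metadata}


def write_symmetry_geojson(diagram: SymmetryDiagram, path: str | Path) -> None:
    Path(path).write_text(json.dumps(symmetry_geojson(diagram)))


def write_ses_csv(m: SESMap, path: str | Path) -> None:
    m.table.to_csv(path, index=False)


def read_ses_csv(path: str | Path) -> SESMap:
    table = pd.read_csv(path, keep_default_na=False,
                        na_values=["", "nan", "NaN"])
    if "flag" in table.columns:
        table["flag"] = table["flag"].fillna("")
    return SESMap(
        table=table,
        cutoff=float(table["cutoff"].iloc[0]) if len(table) else float("nan"),
        R=int(table["R"].iloc[0]) if len(table) else 0,
    )
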