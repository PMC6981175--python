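"""Within-ecoregion distance analysis.

Under niche conservatism, range expansion respects ecoregion boundaries,
so the null-model deviation (SES) of asymmetry should decay with distance
from the ecotone: cells deep inside a large region see quasi-symmetric
species turnover, cells near the boundary see ranges piled up against it.
This module selects the interior cells of a region (optionally below an
elevation cap and minus an explicit exclusion list), regresses SES on
boundary distance by ordinary least squares, and tests the residuals for
normality with a one-sample Kolmogorov–Smirnov test.

The KS test standardises residuals by their own mean and sample standard
deviation, so (as in the classical Lilliefors situation) its p-value is
approximate; it is reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .domain import BoundaryDistanceMap, GridDomain
from .errors import ValidationError
from .nullmodel import SESMap


def interior_cells(
    domain: GridDomain,
    region_label: int,
    elevation_cap: float | None = None,
    exclusions: Iterable[int] = (),
) -> np.ndarray:
    """External ids of region cells below the cap, minus exclusions."""
    if domain.ecoregion is None:
        raise ValidationError("domain has no ecoregion layer")
    mask = domain.ecoregion == int(region_label)
    if not mask.any():
        raise ValidationError(f"ecoregion label {region_label!r} absent from domain")
    if elevation_cap is not None:
        if domain.elevation_m is None:
            raise ValidationError("elevation cap given but domain has no elevation layer")
        mask &= domain.elevation_m < float(elevation_cap)
    ids = set(int(c) for c in domain.cell_ids[mask])
    ids -= {int(c) for c in exclusions}
    return np.array(sorted(ids), dtype=np.int64)


@dataclass
class EcotoneRegression:
    """OLS of SES on boundary distance, with residual diagnostics."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    distances: np.ndarray
    ses_values: np.ndarray
    residuals: np.ndarray
    ks_stat: float
    ks_p: float  # approximate: residual mean/sd estimated from the data

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_stderr": self.slope_stderr,
            "ks_stat": self.ks_stat,
            "ks_p": self.ks_p,
        }


def distance_regression(
    cells: Iterable[int],
    distances: BoundaryDistanceMap | Mapping[int, float],
    ses: SESMap | Mapping[int, float],
    domain: GridDomain | None = None,
) -> EcotoneRegression:
    """Least-squares regression of per-cell SES on boundary distance.

    ``distances`` may be a :class:`BoundaryDistanceMap` (requires
    ``domain`` for id lookup) or any mapping from cell id to distance —
    the hook through which externally computed distances (e.g. km) enter
    without changing the contract.  Cells with non-finite SES or distance
    are dropped.
    """
    cells = [int(c) for c in cells]

    def _dist(cid: int) -> float:
        if isinstance(distances, BoundaryDistanceMap):
            if domain is None:
                raise ValidationError("BoundaryDistanceMap input requires the domain")
            return distances.value(domain, cid)
        return float(distances[cid])

    if isinstance(ses, SESMap):
        lookup = dict(zip(ses.table["cell_id"], ses.table["ses"]))
    else:
        lookup = {int(k): float(v) for k, v in ses.items()}

    d, y = [], []
    for cid in cells:
        if cid not in lookup:
            continue
        dv, sv = _dist(cid), lookup[cid]
        if np.isfinite(dv) and np.isfinite(sv):
            d.append(dv)
            y.append(sv)
    d = np.asarray(d)
    y = np.asarray(y)
    if len(d) < 3:
        raise ValidationError(f"need >= 3 cells with finite SES, got {len(d)}")
    if np.var(d) == 0:
        raise ValidationError("zero variance in boundary distances")

    fit = stats.linregress(d, y)
    resid = y - (fit.intercept + fit.slope * d)
    sd = resid.std(ddof=1)
    if sd == 0:
        ks_stat, ks_p = 0.0, 1.0
    else:
        ks_stat, ks_p = stats.kstest((resid - resid.mean()) / sd, "norm")
    return EcotoneRegression(
        n=len(d),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_stderr=float(fit.stderr),
        distances=d,
        ses_values=y,
        residuals=resid,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
    )
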