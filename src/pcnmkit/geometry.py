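"""Site geometry: weighted centroids, Euclidean distances, MST truncation threshold.

Coordinates are planar meters (projected grid, e.g. meters north of the
equator / east of a reference meridian). The module never reprojects;
longitude/latitude input must be rejected upstream unless the caller
explicitly asserts the coordinates are planar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "validate_sites",
    "weighted_centroid",
    "sites_from_settlements",
    "pairwise_distance_matrix",
    "mst_threshold",
]

SITE_COLUMNS = ("site_id", "x", "y")
SETTLEMENT_COLUMNS = ("site_id", "x", "y", "population")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of Euclidean intersite distances.

    Attributes
    ----------
    site_ids : list
        Site identifiers in matrix row/column order.
    values : ndarray, shape (n, n)
        Nonnegative symmetric distances, zero diagonal.
    """

    site_ids: list = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.site_ids) != d.shape[0]:
            raise ValueError("site_ids length does not match matrix order")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", d)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def validate_sites(sites: pd.DataFrame, *, planar_ok: bool = False) -> pd.DataFrame:
    """Validate a site table (columns site_id, x, y).

    Raises if ids are duplicated, coordinates non-finite, or the coordinate
    ranges look like longitude/latitude degrees (|x| <= 360 and |y| <= 90
    for every site) unless ``planar_ok`` is passed. Treating degrees as
    meters silently collapses the geometry, so it is refused by default.
    """
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    out = sites.loc[:, list(SITE_COLUMNS)].copy()
    out["x"] = pd.to_numeric(out["x"], errors="raise")
    out["y"] = pd.to_numeric(out["y"], errors="raise")
    if out["site_id"].duplicated().any():
        dup = out.loc[out["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"duplicate site_id: {dup!r}")
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise ValueError("site coordinates must be finite")
    looks_degrees = (out["x"].abs() <= 360).all() and (out["y"].abs() <= 90).all()
    if looks_degrees and not planar_ok:
        raise ValueError(
            "coordinates fall inside lon/lat degree ranges; this tool requires "
            "projected planar meters — pass planar_ok=True (or the CLI "
            "--planar flag) if they really are planar"
        )
    return out.reset_index(drop=True)


def weighted_centroid(settlements: pd.DataFrame) -> tuple[float, float]:
    """Population-weighted mean point of one site's settlement concentrations.

    Parameters
    ----------
    settlements : DataFrame with columns x, y, population (one site's rows).

    Returns
    -------
    (x, y) : the weighted arithmetic mean of the settlement coordinates.
    """
    if len(settlements) == 0:
        raise ValueError("no settlements supplied")
    w = np.asarray(settlements["population"], dtype=float)
    if np.any(w < 0) or not np.isfinite(w).all():
        raise ValueError("populations must be finite and nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total settlement population must be positive")
    x = float(np.average(settlements["x"], weights=w))
    y = float(np.average(settlements["y"], weights=w))
    return x, y


def sites_from_settlements(
    settlements: pd.DataFrame, *, planar_ok: bool = False
) -> pd.DataFrame:
    """Collapse a settlement table to one weighted-centroid point per site."""
    missing = [c for c in SETTLEMENT_COLUMNS if c not in settlements.columns]
    if missing:
        raise ValueError(f"settlement table missing columns: {missing}")
    rows = []
    for site_id, grp in settlements.groupby("site_id", sort=False):
        x, y = weighted_centroid(grp)
        rows.append({"site_id": site_id, "x": x, "y": y})
    return validate_sites(pd.DataFrame(rows), planar_ok=planar_ok)


def pairwise_distance_matrix(
    sites: pd.DataFrame, *, planar_ok: bool = False
) -> DistanceMatrix:
    """Euclidean distance matrix D among sites, in the table's row order."""
    sites = validate_sites(sites, planar_ok=planar_ok)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites for a distance matrix")
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    d = squareform(pdist(xy, metric="euclidean"))
    off = d[np.triu_indices_from(d, k=1)]
    if np.any(off == 0):
        warnings.warn(
            "distinct sites share exact coordinates; eigenvector scores for "
            "such pairs are not unique",
            stacklevel=2,
        )
    return DistanceMatrix(site_ids=list(sites["site_id"]), values=d)


def mst_threshold(D: DistanceMatrix) -> float:
    """Longest edge of a minimum spanning tree over the complete graph on D.

    This is the smallest t such that the graph with edges {d_ij <= t} keeps
    all sites connected; distances beyond it are replaced by a large
    constant before eigendecomposition.
    """
    if D.n < 2:
        raise ValueError("need at least 2 sites for an MST threshold")
    d = D.values
    # csgraph treats 0 as "no edge" in dense input; shift all off-diagonal
    # weights by a constant (MST edge set is invariant) so zero-distance
    # duplicate sites stay in the graph, then shift back.
    shift = 1.0 if np.any(d[np.triu_indices_from(d, k=1)] == 0) else 0.0
    g = d + shift
    np.fill_diagonal(g, 0.0)
    mst = minimum_spanning_tree(g)
    t = float(mst.toarray().max() - shift)
    if t <= 0:
        warnings.warn("all intersite distances are zero", stacklevel=2)
        t = 0.0
    return t
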