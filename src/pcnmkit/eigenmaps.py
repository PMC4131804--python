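"""Spatial eigenvector maps from truncated distance matrices.

The construction is principal coordinates of neighbour matrices (PCNM):
distances beyond a truncation threshold t (the longest minimum-spanning-tree
edge) are replaced by a large constant (4t), the truncated matrix is
Gower-double-centered as in principal coordinate analysis, and the
eigenvectors with positive eigenvalues are retained. Columns are ordered by
descending eigenvalue, broad spatial scales first; each column is a per-site
"site score" pattern whose Moran's I decreases, roughly, with column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DistanceMatrix

__all__ = [
    "ConnectivityMatrix",
    "EigenMap",
    "truncate_distance_matrix",
    "compute_eigenmap",
    "morans_i",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Truncated connectivity matrix W: w_ij = d_ij if d_ij <= t, else m*t."""

    values: np.ndarray = field(repr=False)
    threshold: float = 0.0
    multiplier: float = 4.0
    site_ids: list | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EigenMap:
    """Positive-eigenvalue spatial eigenvectors.

    Attributes
    ----------
    eigenvalues : ndarray, shape (m,)
        Strictly positive, sorted descending.
    scores : ndarray, shape (n, m)
        Per-site eigenvector scores; column k (0-based) is spatial vector
        k+1. Columns are unit-norm, zero-mean and mutually orthogonal.
    site_ids : list
    centering : str
        "gower_sq" (standard PCNM: double-center -1/2 * W**2) or "raw".
    """

    eigenvalues: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)
    site_ids: list = field(repr=False)
    centering: str = "gower_sq"

    @property
    def n_sites(self) -> int:
        return self.scores.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.scores.shape[1]

    def scaled_scores(self) -> np.ndarray:
        """Scores rescaled by sqrt(eigenvalue), for distance reconstruction."""
        return self.scores * np.sqrt(self.eigenvalues)


def truncate_distance_matrix(
    D: DistanceMatrix, t: float, multiplier: float = 4.0
) -> ConnectivityMatrix:
    """Apply the truncation rule w_ij = d_ij if d_ij <= t else multiplier*t.

    The threshold is inclusive; the diagonal stays zero. The input D is
    unmodified.
    """
    if t <= 0:
        raise ValueError("truncation threshold t must be positive")
    if multiplier <= 1:
        raise ValueError("truncation multiplier must exceed 1")
    w = D.values.copy()
    w[w > t] = multiplier * t
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        values=w, threshold=float(t), multiplier=float(multiplier),
        site_ids=list(D.site_ids),
    )


def _double_center(a: np.ndarray) -> np.ndarray:
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic).

    Ties on magnitude are broken by the lowest site index, which argmax
    already gives.
    """
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, j])))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def compute_eigenmap(
    W: ConnectivityMatrix,
    positivity_tol: float = 1e-9,
    centering: str = "gower_sq",
) -> EigenMap:
    """Extract positive-eigenvalue eigenvectors from the centered W.

    ``gower_sq`` performs classical principal coordinate analysis treating W
    as a distance matrix: A = -1/2 * W**2 is double-centered (row means,
    column means, grand mean) and eigendecomposed; eigenpairs with
    eigenvalue > positivity_tol * max(eigenvalue) are kept, sorted
    descending. ``raw`` double-centers W itself (sensitivity option).

    Score columns are unit-norm with a deterministic sign (largest-magnitude
    entry positive).
    """
    n = W.n
    if n < 3:
        raise ValueError("need at least 3 sites for an eigenmap")
    if centering == "gower_sq":
        a = -0.5 * W.values**2
    elif centering == "raw":
        a = W.values.astype(float)
    else:
        raise ValueError(f"unknown centering {centering!r}")
    g = _double_center(a)
    g = (g + g.T) / 2.0  # enforce exact symmetry for eigh
    lam, vec = np.linalg.eigh(g)
    lam, vec = lam[::-1], vec[:, ::-1]
    lam_max = lam[0]
    if lam_max <= 0:
        raise ValueError("no positive eigenvalue: degenerate connectivity matrix")
    keep = lam > positivity_tol * lam_max
    if not keep.any():
        raise ValueError("no eigenvalue above the positivity tolerance")
    lam, vec = lam[keep], vec[:, keep]
    vec = _fix_signs(vec)
    return EigenMap(
        eigenvalues=lam,
        scores=vec,
        site_ids=list(W.site_ids) if W.site_ids is not None else list(range(n)),
        centering=centering,
    )


def morans_i(
    values: np.ndarray, D: DistanceMatrix, t: float
) -> tuple[float, float]:
    """Moran's I with binary within-threshold neighbour weights.

    Weights are w*_ij = 1 if 0 < d_ij <= t else 0 — the truncation constant
    used for the eigendecomposition is a computational device, not a
    meaningful weight, so it plays no role here.

    Returns
    -------
    (I, expected) where expected = -1/(n-1), the no-autocorrelation
    reference; I above it indicates positive spatial autocorrelation.
    """
    x = np.asarray(values, dtype=float)
    n = D.n
    if x.shape != (n,):
        raise ValueError("values length must match the distance matrix order")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")
    w = ((D.values > 0) & (D.values <= t)).astype(float)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("no neighbour pairs within the threshold")
    num = float(z @ w @ z)
    i_stat = (n / s0) * num / denom
    return i_stat, -1.0 / (n - 1)
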