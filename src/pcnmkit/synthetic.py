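"""Synthetic study systems: site layouts, planted spatial responses, case counts.

No registry of area-level disease counts with coordinates is distributable
with this package, so every stage is exercised on generated data that
emulates the study design: an irregular planar layout of a few hundred
sites, an area-level rate whose mean structure is a linear combination of
known spatial eigenvectors, and Poisson case counts over person-year
denominators. All randomness flows through one seeded generator per call;
a fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eigenmaps import EigenMap, compute_eigenmap, truncate_distance_matrix
from .geometry import mst_threshold, pairwise_distance_matrix
from .incidence import pooled_rate
from .modelfit import PCNMRegression

__all__ = [
    "make_grid_sites",
    "make_random_sites",
    "simulate_response",
    "simulate_case_counts",
    "eigenmap_for_sites",
    "recovery_experiment",
]

# Finland-scale defaults: ~320 areas in a 2:1 extent of about 1,100 km,
# person-years per area on the order of 10^5 per year over decades.
FINLAND_N = 320
FINLAND_EXTENT = 1_100_000.0  # meters


def make_grid_sites(nx: int, ny: int, spacing: float = 1000.0) -> pd.DataFrame:
    """Regular nx-by-ny lattice of sites; its MST threshold equals spacing."""
    if nx < 2 or ny < 2:
        raise ValueError("grid needs nx, ny >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return pd.DataFrame({
        "site_id": [f"g{i:04d}" for i in range(nx * ny)],
        "x": xs.ravel() * spacing,
        "y": ys.ravel() * spacing,
    })


def make_random_sites(
    n: int, extent: float = FINLAND_EXTENT, seed: int = 0, aspect: float = 0.5
) -> pd.DataFrame:
    """Uniform random sites in an extent-by-(aspect*extent) rectangle.

    The default rectangle is a 2:1 Finland-scale stand-in (about 1,100 km by
    550 km); real national geographies are external data by policy.
    """
    if n < 3:
        raise ValueError("need at least 3 sites")
    if extent <= 0:
        raise ValueError("extent must be positive")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 1, size=(n, 2)) * np.array([aspect * extent, extent])
    return pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(n)],
        "x": xy[:, 0],
        "y": xy[:, 1],
    })


def eigenmap_for_sites(sites: pd.DataFrame, multiplier: float = 4.0) -> EigenMap:
    """Convenience: distance matrix -> MST threshold -> truncation -> eigenmap."""
    d = pairwise_distance_matrix(sites)
    t = mst_threshold(d)
    return compute_eigenmap(truncate_distance_matrix(d, t, multiplier))


@dataclass(frozen=True)
class ResponseTruth:
    """Replayable record of a planted response."""

    planted: tuple = ()  # 1-based eigenvector numbers
    betas: tuple = ()
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    noise: np.ndarray = field(default=None, repr=False)


def simulate_response(
    eigenmap: EigenMap,
    planted: list[int],
    betas: list[float],
    noise_sd: float,
    seed: int,
    intercept: float = 0.0,
) -> tuple[np.ndarray, ResponseTruth]:
    """Planted linear response y = intercept + sum beta_j * score_j + noise.

    ``planted`` uses 1-based eigenvector numbers into the map's retained
    columns. The truth record carries the exact noise vector, so y is
    recomputable from it.
    """
    if len(planted) != len(betas):
        raise ValueError("planted and betas must have equal length")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    idx = np.asarray(planted, dtype=int) - 1
    if idx.size and (idx.min() < 0 or idx.max() >= eigenmap.n_vectors):
        raise ValueError("planted eigenvector number outside retained columns")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=eigenmap.n_sites)
    y = intercept + eigenmap.scores[:, idx] @ np.asarray(betas, float) + noise
    truth = ResponseTruth(
        planted=tuple(planted), betas=tuple(betas), intercept=intercept,
        noise_sd=noise_sd, seed=seed, noise=noise,
    )
    return y, truth


def simulate_case_counts(
    true_rates: pd.Series,
    py_per_site: float | pd.Series,
    seed: int,
    n_years: int = 1,
    scale: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson case counts from true rates (per ``scale`` person-years).

    cases_i,year ~ Poisson(rate_i * py_i / scale), independently per year;
    pooling the output reproduces the true rates without bias. Returns
    (case table, person-years table) in the standard long formats.
    """
    rates = np.asarray(true_rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("true rates must be nonnegative")
    site_ids = list(true_rates.index)
    py = np.broadcast_to(
        np.asarray(py_per_site, dtype=float), (len(site_ids),)
    ).copy()
    if (py <= 0).any():
        raise ValueError("person-years must be positive")
    rng = np.random.default_rng(seed)
    case_rows, py_rows = [], []
    for year in range(n_years):
        cases = rng.poisson(rates * py / scale)
        for sid, c, p in zip(site_ids, cases, py):
            case_rows.append(
                {"site_id": sid, "year": year, "sex": "all", "cases": int(c)}
            )
            py_rows.append(
                {"site_id": sid, "year": year, "sex": "all",
                 "person_years": float(p)}
            )
    return pd.DataFrame(case_rows), pd.DataFrame(py_rows)


def recovery_experiment(
    sites: pd.DataFrame,
    planted: list[int],
    betas: list[float],
    noise_sd: float,
    reps: int,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Repeatedly plant and re-select; measure recovery under both rules.

    Per replicate the full planted response is regenerated and forward
    selection is run under the double stopping criterion and under
    alpha-only entry (paired seeds). Reports sensitivity (fraction of
    planted vectors recovered), false-inclusion rate (fraction of selected
    vectors that were not planted), and mean selected counts.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    emap = eigenmap_for_sites(sites)
    planted_set = set(planted)
    rng = np.random.default_rng(seed)
    sens, fips, n_double, n_alpha, all_recovered = [], [], [], [], []
    for _ in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        y, _truth = simulate_response(emap, planted, betas, noise_sd, rep_seed)
        res_d = PCNMRegression(y, emap, alpha=alpha).fit(selection="double_stop")
        res_a = PCNMRegression(y, emap, alpha=alpha).fit(selection="alpha_only")
        sel = set(res_d.selected)
        if planted_set:
            sens.append(len(sel & planted_set) / len(planted_set))
            all_recovered.append(planted_set <= sel)
        fips.append(len(sel - planted_set) / max(len(sel), 1))
        n_double.append(len(res_d.selected))
        n_alpha.append(len(res_a.selected))
    return {
        "sensitivity": float(np.mean(sens)) if sens else float("nan"),
        "all_planted_recovered_rate": (
            float(np.mean(all_recovered)) if all_recovered else float("nan")
        ),
        "false_inclusion_rate": float(np.mean(fips)),
        "mean_selected_double_stop": float(np.mean(n_double)),
        "mean_selected_alpha_only": float(np.mean(n_alpha)),
        "reps": reps,
    }
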