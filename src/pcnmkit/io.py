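"""Delimited-text readers/writers, GeoJSON score export, pipeline config & run.

Dialect: comma-separated UTF-8 with a required header row and "." decimal;
tab is accepted via ``delimiter="\\t"``. Site/settlement tables carry
site_id, x, y [, population]; case and person-years tables carry site_id
[, year] [, sex] and cases / person_years.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eigenmaps import EigenMap, compute_eigenmap, truncate_distance_matrix
from .geometry import (
    mst_threshold,
    pairwise_distance_matrix,
    sites_from_settlements,
    validate_sites,
)
from .incidence import pooled_rate, prepare_response
from .modelfit import PCNMRegression

logger = logging.getLogger("pcnmkit")

__all__ = [
    "read_sites",
    "read_settlements",
    "read_cases",
    "read_person_years",
    "write_eigenmap",
    "eigenmap_to_geojson",
    "PipelineConfig",
    "load_config",
    "run_pipeline",
]


def _read_table(path, required: dict[str, type], optional: dict[str, type],
                delimiter: str = ",") -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"site_id": str})
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, typ in {**required, **optional}.items():
        if col not in df.columns or typ is str:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(
                f"{path}: missing value in column {col!r} at line {line}"
            )
        df[col] = coerced
    logger.info("read %s: %d rows", path, len(df))
    return df


def read_sites(path, delimiter: str = ",", planar_ok: bool = False) -> pd.DataFrame:
    df = _read_table(path, {"site_id": str, "x": float, "y": float}, {},
                     delimiter)
    return validate_sites(df, planar_ok=planar_ok)


def read_settlements(path, delimiter: str = ",") -> pd.DataFrame:
    return _read_table(
        path,
        {"site_id": str, "x": float, "y": float, "population": float},
        {}, delimiter,
    )


def read_cases(path, delimiter: str = ",") -> pd.DataFrame:
    return _read_table(path, {"site_id": str, "cases": int},
                       {"year": int, "sex": str}, delimiter)


def read_person_years(path, delimiter: str = ",") -> pd.DataFrame:
    return _read_table(path, {"site_id": str, "person_years": float},
                       {"year": int, "sex": str}, delimiter)


def check_site_overlap(sites: pd.DataFrame, other: pd.DataFrame,
                       what: str) -> None:
    extra = sorted(set(other["site_id"]) - set(sites["site_id"]))
    if extra:
        raise ValueError(f"{what} table has site(s) absent from the site "
                         f"table: {extra}")


def write_eigenmap(emap: EigenMap, path, delimiter: str = ",") -> None:
    """Scores table (site_id, score_1..score_m) plus .eigenvalues sidecar."""
    path = Path(path)
    cols = {f"score_{k + 1}": emap.scores[:, k] for k in range(emap.n_vectors)}
    pd.DataFrame({"site_id": emap.site_ids, **cols}).to_csv(
        path, sep=delimiter, index=False
    )
    side = path.with_suffix(path.suffix + ".eigenvalues")
    pd.DataFrame({
        "vector": np.arange(1, emap.n_vectors + 1),
        "eigenvalue": emap.eigenvalues,
    }).to_csv(side, sep=delimiter, index=False)


def eigenmap_to_geojson(emap: EigenMap, sites: pd.DataFrame) -> dict:
    """Point features with per-vector score properties, for mapping."""
    by_id = sites.set_index("site_id")
    features = []
    for i, sid in enumerate(emap.site_ids):
        row = by_id.loc[sid]
        props = {"site_id": str(sid)}
        props.update({
            f"score_{k + 1}": float(emap.scores[i, k])
            for k in range(emap.n_vectors)
        })
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}


@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults mirror the reference analysis."""

    sites: str | None = None
    settlements: str | None = None
    cases: str | None = None
    person_years: str | None = None
    sex_filter: str = "all"
    alpha: float = 0.05
    multiplier: float = 4.0
    positivity_tol: float = 1e-9
    transform: str = "auto"  # auto | always | never
    outlier_cutoff: float = 3.0
    scale: float = 1000.0
    delimiter: str = ","
    planar_ok: bool = False
    outdir: str = "pcnmkit_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.multiplier <= 1:
            raise ValueError("multiplier must exceed 1")
        if self.sites is None and self.settlements is None:
            raise ValueError("config needs a sites or settlements table")

    def digest(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute geometry -> eigenmaps -> incidence -> modelfit and write outputs.

    All results are computed before any file is written, so a failing stage
    leaves no partial output. Returns the machine-readable report; the
    human-readable summary contains no number absent from it.
    """
    delim = config.delimiter
    try:
        if config.settlements:
            settlements = read_settlements(config.settlements, delim)
            sites = sites_from_settlements(settlements,
                                           planar_ok=config.planar_ok)
        else:
            sites = read_sites(config.sites, delim, planar_ok=config.planar_ok)
    except Exception as exc:
        raise RuntimeError(f"stage geometry(read): {exc}") from exc

    try:
        dmat = pairwise_distance_matrix(sites, planar_ok=True)
        t = mst_threshold(dmat)
        emap = compute_eigenmap(
            truncate_distance_matrix(dmat, t, config.multiplier),
            positivity_tol=config.positivity_tol,
        )
    except Exception as exc:
        raise RuntimeError(f"stage eigenmaps: {exc}") from exc

    try:
        cases = read_cases(config.cases, delim)
        py = read_person_years(config.person_years, delim)
        check_site_overlap(sites, cases, "case")
        check_site_overlap(sites, py, "person-years")
        rates = pooled_rate(cases, py, sex_filter=config.sex_filter,
                            scale=config.scale)
        rates = rates.reindex([str(s) for s in emap.site_ids])
        if rates.isna().any():
            miss = sorted(rates.index[rates.isna()])
            raise ValueError(f"no rate for site(s): {miss}")
        response = prepare_response(rates, alpha=config.alpha,
                                    transform=config.transform)
    except Exception as exc:
        raise RuntimeError(f"stage incidence: {exc}") from exc

    try:
        model = PCNMRegression(response, emap, alpha=config.alpha)
        results = model.fit(selection="double_stop")
        outliers = results.outlier_report(cutoff=config.outlier_cutoff)
    except Exception as exc:
        raise RuntimeError(f"stage modelfit: {exc}") from exc

    report = {
        "config_digest": config.digest(),
        "n_sites": int(emap.n_sites),
        "threshold_t": float(t),
        "n_positive_eigenvectors": int(emap.n_vectors),
        "transform": response.transform,
        "ks_p": float(response.ks_p),
        "selected_vectors": list(results.selected),
        "beta": [float(b) for b in results.params],
        "beta_std": [float(b) for b in results.beta_std],
        "r": results.r,
        "r2": results.r2,
        "r2_adj": results.r2_adj,
        "r2_adj_full": float(results.trace.r2_adj_full),
        "r2_adj_alpha_only": None,  # filled below
        "stop_reason": results.trace.stop_reason,
        "selection_steps": [
            {"vector": v, "p_enter": p, "r2_adj": r}
            for v, p, r in results.trace.steps
        ],
        "outliers_threshold": [
            str(s) for s, m in zip(emap.site_ids, outliers.threshold_mask) if m
        ],
        "outliers_chauvenet": [
            str(s) for s, m in zip(emap.site_ids, outliers.chauvenet_mask) if m
        ],
        "chauvenet_critical": float(outliers.chauvenet_critical),
        "seed": config.seed,
    }
    alpha_only = model.fit(selection="alpha_only")
    report["r2_adj_alpha_only"] = alpha_only.r2_adj
    report["selected_alpha_only"] = list(alpha_only.selected)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_eigenmap(emap, outdir / "eigenmap.csv", delim)
    with open(outdir / "scores.geojson", "w") as fh:
        json.dump(eigenmap_to_geojson(emap, sites), fh)
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "model_report.txt", "w") as fh:
        fh.write(results.summary() + "\n")
    pd.DataFrame({
        "site_id": [str(s) for s in emap.site_ids],
        "residual": results.resid,
        "residual_studentized": results.resid_studentized,
        "outlier_threshold": outliers.threshold_mask,
        "outlier_chauvenet": outliers.chauvenet_mask,
    }).to_csv(outdir / "residuals.csv", sep=delim, index=False)
    logger.info(
        "pipeline done: t=%.1f m, %d positive vectors, transform=%s, stop=%s",
        t, emap.n_vectors, response.transform, results.trace.stop_reason,
    )
    return report
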