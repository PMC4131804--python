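"""OLS on spatial eigenvectors with forward selection and a double stopping rule.

The model class follows the statsmodels convention: ``PCNMRegression`` holds
the response and the candidate eigenvector scores; ``fit()`` returns a
``PCNMResults`` object carrying coefficients, standardized coefficients,
r/r2/adjusted r2, studentized residuals, outlier masks and a ``summary()``
table. Forward selection adds, at each step, the candidate with the smallest
entry p-value provided p < alpha, and stops either when no candidate clears
alpha or when the running adjusted r2 reaches the adjusted r2 of the model
using ALL candidate vectors ("double stopping criterion") — many
eigenvectors can proxy the same spatial process, so alpha-only entry
inflates the fit.

Eigenvectors are numbered 1-based throughout the public API (vector 1 =
broadest spatial scale), matching the PCNM literature's PCNM1, PCNM2, ...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .eigenmaps import EigenMap
from .incidence import ResponseVector

__all__ = [
    "PCNMRegression",
    "PCNMResults",
    "SelectionTrace",
    "OutlierReport",
    "adjusted_r2",
    "fit_ols",
    "forward_select_double_stop",
    "standardized_residuals",
    "flag_outliers_threshold",
    "chauvenet_critical",
    "chauvenet_outliers",
]


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted coefficient of determination 1 - (1-r2)(n-1)/(n-k-1)."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must lie in [0, 1]")
    if n <= k + 1:
        raise ValueError("adjusted r2 requires n > k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class SelectionTrace:
    """Forward-selection path: one (vector, entry p, adjusted r2) per step."""

    steps: list = field(default_factory=list)  # (vector, p_enter, r2_adj)
    r2_adj_full: float = np.nan
    stop_reason: str = ""  # alpha_exhausted | r2_ceiling_reached | no_candidates


@dataclass(frozen=True)
class OutlierReport:
    """Outlying sites under the |z| > cutoff rule and Chauvenet's criterion."""

    threshold_mask: np.ndarray = field(repr=False)
    chauvenet_mask: np.ndarray = field(repr=False)
    cutoff: float = 3.0
    chauvenet_critical: float = np.nan
    site_ids: list | None = field(default=None, repr=False)


class PCNMResults:
    """Fitted eigenvector regression.

    Attributes
    ----------
    selected : list of int
        1-based eigenvector numbers in the design, in entry order.
    params : ndarray
        Intercept followed by slopes, in ``selected`` order.
    beta_std : ndarray
        Standardized slopes beta_j * sd(x_j) / sd(y).
    r, r2, r2_adj : float
    resid : ndarray
    resid_studentized : ndarray
        Internally studentized residuals e_i / (s * sqrt(1 - h_ii)).
    trace : SelectionTrace or None
        Present when the model came from forward selection.
    """

    def __init__(self, model: "PCNMRegression", selected: list[int],
                 sm_results, trace: SelectionTrace | None = None):
        self.model = model
        self.selected = list(selected)
        self._sm = sm_results
        self.trace = trace
        self.nobs = int(sm_results.nobs)
        self.k = len(selected)
        self.params = np.asarray(sm_results.params)
        self.pvalues = np.asarray(sm_results.pvalues)
        self.r2 = float(sm_results.rsquared) if self.k else 0.0
        self.r2_adj = adjusted_r2(self.r2, self.nobs, self.k)
        self.r = float(np.sqrt(self.r2))
        self.resid = np.asarray(sm_results.resid)
        sd_y = model.y.std(ddof=1)
        if self.k:
            sd_x = model.scores_for(self.selected).std(axis=0, ddof=1)
            self.beta_std = self.params[1:] * sd_x / sd_y
        else:
            self.beta_std = np.array([])
        self._resid_studentized: np.ndarray | None = None

    @property
    def resid_studentized(self) -> np.ndarray:
        if self._resid_studentized is None:
            self._resid_studentized = standardized_residuals(self)
        return self._resid_studentized

    def outlier_report(self, cutoff: float = 3.0) -> OutlierReport:
        z = self.resid_studentized
        crit = chauvenet_critical(len(z))
        return OutlierReport(
            threshold_mask=flag_outliers_threshold(z, cutoff),
            chauvenet_mask=chauvenet_outliers(z),
            cutoff=cutoff,
            chauvenet_critical=crit,
            site_ids=self.model.site_ids,
        )

    def summary(self) -> str:
        lines = [
            "Spatial eigenvector regression (OLS)",
            f"  n sites:            {self.nobs}",
            f"  response transform: {self.model.response_transform}",
            f"  vectors in model:   {self.k}"
            + (f"  -> {self.selected}" if self.k else ""),
            f"  r:                  {self.r:.3f}",
            f"  r2:                 {self.r2:.3f}",
            f"  adjusted r2:        {self.r2_adj:.3f}",
        ]
        if self.trace is not None:
            lines += [
                f"  adjusted r2 (all candidates): {self.trace.r2_adj_full:.3f}",
                f"  stop reason:        {self.trace.stop_reason}",
            ]
        if self.k:
            lines.append("  vector      beta    beta_std   p-value")
            for j, v in enumerate(self.selected):
                lines.append(
                    f"  PCNM{v:<5d} {self.params[j + 1]:9.4f} "
                    f"{self.beta_std[j]:9.4f}  {self.pvalues[j + 1]:.2e}"
                )
        rep = self.outlier_report()
        lines.append(
            f"  outliers |z|>{rep.cutoff:g}: {int(rep.threshold_mask.sum())};"
            f" Chauvenet (crit |z|={rep.chauvenet_critical:.2f}):"
            f" {int(rep.chauvenet_mask.sum())}"
        )
        return "\n".join(lines)


class PCNMRegression:
    """Regression of an area-level response on spatial eigenvector scores.

    Parameters
    ----------
    y : ResponseVector or array-like
        Per-site response (e.g. pooled incidence rate, possibly log10).
    eigenmap : EigenMap or ndarray (n, m)
        Candidate spatial vectors, broadest first.
    alpha : float
        Entry significance level for forward selection.
    """

    def __init__(self, y, eigenmap, alpha: float = 0.05):
        if isinstance(y, ResponseVector):
            self.y = np.asarray(y.values, dtype=float)
            self.site_ids = list(y.site_ids)
            self.response_transform = y.transform
        else:
            self.y = np.asarray(y, dtype=float)
            self.site_ids = None
            self.response_transform = "none"
        if isinstance(eigenmap, EigenMap):
            self.scores = eigenmap.scores
            if self.site_ids is not None and list(eigenmap.site_ids) != self.site_ids:
                raise ValueError("response and eigenmap site orders differ")
            if self.site_ids is None:
                self.site_ids = list(eigenmap.site_ids)
        else:
            self.scores = np.asarray(eigenmap, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != len(self.y):
            raise ValueError("scores must be (n_sites, m) matching y")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.alpha = float(alpha)
        self.n = len(self.y)
        self.m = self.scores.shape[1]

    def scores_for(self, vectors: list[int]) -> np.ndarray:
        """Score columns for 1-based vector numbers, in the given order."""
        idx = np.asarray(vectors, dtype=int) - 1
        if len(idx) != len(set(idx.tolist())):
            raise ValueError("duplicated eigenvector in design")
        if idx.size and (idx.min() < 0 or idx.max() >= self.m):
            raise ValueError("eigenvector number out of range")
        return self.scores[:, idx]

    def fit(self, vectors: list[int] | None = None,
            selection: str | None = None) -> PCNMResults:
        """Fit by explicit vector list, or by forward selection.

        ``selection`` is "double_stop" (default when no vectors are given)
        or "alpha_only".
        """
        if vectors is not None and selection is not None:
            raise ValueError("pass either vectors or selection, not both")
        if vectors is not None:
            return self._fit_exact(vectors)
        return self._fit_forward(selection or "double_stop")

    # -- internals ---------------------------------------------------------

    def _fit_exact(self, vectors: list[int],
                   trace: SelectionTrace | None = None) -> PCNMResults:
        vectors = list(vectors)
        if self.n <= len(vectors) + 1:
            raise ValueError(
                f"cannot fit {len(vectors)} predictors with n={self.n}"
            )
        x = sm.add_constant(self.scores_for(vectors), has_constant="add")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design is rank deficient (collinear columns)")
        res = sm.OLS(self.y, x).fit()
        return PCNMResults(self, vectors, res, trace)

    def _entry_pvalues(self, design: np.ndarray, resid: np.ndarray,
                       sse: float, candidates: np.ndarray):
        """Exact partial-F entry tests for every candidate column.

        Orthogonalizes each candidate against the current design via its QR
        factorization; the SSE drop from adding candidate x is
        (x_perp . e)^2 / (x_perp . x_perp), and F = drop / new MSE with
        (1, n-k-2) df. Identical to the entering coefficient's t-test.
        """
        n, kp1 = design.shape
        q, _ = np.linalg.qr(design)
        xc = self.scores[:, candidates]
        xperp = xc - q @ (q.T @ xc)
        ss = np.einsum("ij,ij->j", xperp, xperp)
        ok = ss > 1e-12 * np.einsum("ij,ij->j", xc, xc)
        proj = xperp.T @ resid
        drop = np.zeros_like(ss)
        drop[ok] = proj[ok] ** 2 / ss[ok]
        df2 = n - kp1 - 1
        sse_new = np.maximum(sse - drop, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = drop / (sse_new / df2)
        p = np.where(ok, stats.f.sf(f, 1, df2), 1.0)
        p = np.where(sse_new / df2 <= 0, 0.0, p)
        return p, drop

    def _full_ceiling(self) -> float:
        """Adjusted r2 of the all-candidate model, the selection ceiling."""
        if self.m <= self.n - 2:
            return self._fit_exact(list(range(1, self.m + 1))).r2_adj
        k = self.n // 2
        warnings.warn(
            f"{self.m} candidates with only n={self.n} sites: the "
            f"all-candidate model is not fittable; using the broadest "
            f"{k} vectors for the adjusted-r2 ceiling",
            stacklevel=3,
        )
        return self._fit_exact(list(range(1, k + 1))).r2_adj

    def _fit_forward(self, rule: str) -> PCNMResults:
        if rule not in ("double_stop", "alpha_only"):
            raise ValueError(f"unknown selection rule {rule!r}")
        if self.m == 0:
            raise ValueError("eigenmap has no candidate vectors")
        r2_adj_full = self._full_ceiling() if rule == "double_stop" else np.nan
        selected: list[int] = []
        steps: list[tuple[int, float, float]] = []
        r2_adj_now = 0.0  # intercept-only
        stop = ""
        while True:
            if rule == "double_stop" and r2_adj_now >= r2_adj_full:
                stop = "r2_ceiling_reached"
                break
            remaining = np.array(
                [j for j in range(self.m) if (j + 1) not in selected], dtype=int
            )
            if remaining.size == 0:
                stop = "no_candidates"
                break
            if self.n <= len(selected) + 2:
                # no residual df left for an entry test
                stop = "no_candidates"
                break
            design = sm.add_constant(
                self.scores_for(selected), has_constant="add"
            )
            beta, *_ = np.linalg.lstsq(design, self.y, rcond=None)
            resid = self.y - design @ beta
            sse = float(resid @ resid)
            p, drop = self._entry_pvalues(design, resid, sse, remaining)
            # best: smallest p, ties by larger r2 increment, then lower index
            order = np.lexsort((remaining, -drop, p))
            best = order[0]
            if not p[best] < self.alpha:
                stop = "alpha_exhausted"
                break
            selected.append(int(remaining[best]) + 1)
            r2_adj_now = self._fit_exact(selected).r2_adj
            steps.append((selected[-1], float(p[best]), r2_adj_now))
        trace = SelectionTrace(
            steps=steps, r2_adj_full=float(r2_adj_full), stop_reason=stop
        )
        return self._fit_exact(selected, trace=trace)


def fit_ols(y, scores, vectors: list[int] | None = None) -> PCNMResults:
    """OLS of the response on the given eigenvector columns (with intercept).

    ``vectors`` selects 1-based columns of the eigenmap; omitted means all.
    """
    model = PCNMRegression(y, scores)
    return model.fit(vectors=vectors if vectors is not None
                     else list(range(1, model.m + 1)))


def forward_select_double_stop(
    y, eigenmap, alpha: float = 0.05, rule: str = "double_stop"
) -> tuple[PCNMResults, SelectionTrace]:
    """Forward selection under the double stopping criterion.

    Adds the smallest-p candidate while p < alpha and the running adjusted
    r2 is below the all-candidate model's adjusted r2; returns the stopped
    model and its trace. ``rule="alpha_only"`` disables the ceiling.
    """
    res = PCNMRegression(y, eigenmap, alpha=alpha).fit(selection=rule)
    return res, res.trace


def standardized_residuals(results: PCNMResults) -> np.ndarray:
    """Internally studentized residuals e_i / (s * sqrt(1 - h_ii))."""
    n, k = results.nobs, results.k
    if n <= k + 2:
        raise ValueError("studentization requires n > k + 2")
    infl = results._sm.get_influence()
    h = infl.hat_matrix_diag
    if np.any(h > 1 - 1e-10):
        raise ValueError("leverage of 1: exact interpolation point")
    sse = float(results.resid @ results.resid)
    y = results.model.y
    if sse <= 1e-24 * max(1.0, float(y @ y)):
        return np.zeros(n)  # perfect fit: residuals identically zero
    return np.asarray(infl.resid_studentized_internal)


def flag_outliers_threshold(z: np.ndarray, cutoff: float = 3.0) -> np.ndarray:
    """Boolean mask |z_i| > cutoff."""
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("residuals must be finite")
    return np.abs(z) > cutoff


def chauvenet_critical(n: int) -> float:
    """Critical |z| where n * P(|Z| > z) = 0.5 under the standard normal."""
    if n < 4:
        raise ValueError("Chauvenet's criterion needs at least 4 observations")
    return float(stats.norm.isf(0.25 / n))


def chauvenet_outliers(z: np.ndarray) -> np.ndarray:
    """Single-pass Chauvenet mask: flag where n * P(|Z| > |z_i|) < 0.5."""
    z = np.asarray(z, dtype=float)
    return np.abs(z) > chauvenet_critical(len(z))
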