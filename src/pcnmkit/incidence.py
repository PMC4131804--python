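"""Pooled incidence rates per 1,000 person-years, normality gate, log10 transform.

Rates are unadjusted by design: the point of the pipeline is to ask how much
of the area-level variation spatial eigenvectors alone explain, without
demographic covariates, so no age standardisation is performed. Cases and
person-years are pooled over all available years before division — pooling
is what absorbs zero-case years in small areas. Sex-specific responses
(e.g. breast, prostate analogues) must use the matching sex-specific
denominator; mixing sexes there is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ResponseVector",
    "pooled_rate",
    "ks_normality",
    "prepare_response",
]

VALID_SEX = ("all", "female", "male")


@dataclass(frozen=True)
class ResponseVector:
    """Per-area response: pooled rate, possibly log10-transformed."""

    site_ids: list = field(repr=False)
    values: np.ndarray = field(repr=False)
    transform: str = "none"  # none | log10
    ks_p: float | None = None
    scale: float = 1000.0

    @property
    def n(self) -> int:
        return len(self.values)


def _filter_sex(table: pd.DataFrame, sex_filter: str, what: str) -> pd.DataFrame:
    if "sex" not in table.columns:
        if sex_filter != "all":
            raise ValueError(
                f"{what} table has no sex column but a {sex_filter}-specific "
                "response was requested; sex-specific denominators are mandatory"
            )
        return table
    bad = set(table["sex"]) - set(VALID_SEX)
    if bad:
        raise ValueError(f"{what} table has invalid sex values: {sorted(bad)}")
    if sex_filter == "all":
        return table
    sub = table[table["sex"] == sex_filter]
    if len(sub) == 0:
        raise ValueError(f"{what} table has no rows for sex={sex_filter!r}")
    return sub


def pooled_rate(
    cases: pd.DataFrame,
    person_years: pd.DataFrame,
    sex_filter: str = "all",
    scale: float = 1000.0,
) -> pd.Series:
    """Pooled unadjusted rate per site: scale * sum(cases) / sum(person-years).

    Pooling over all years happens before the division, so areas with
    zero-case years contribute their person-years throughout.

    Returns a Series indexed by site_id.
    """
    if sex_filter not in VALID_SEX:
        raise ValueError(f"sex_filter must be one of {VALID_SEX}")
    c = _filter_sex(cases, sex_filter, "case")
    p = _filter_sex(person_years, sex_filter, "person-years")
    if (c["cases"] < 0).any():
        raise ValueError("case counts must be nonnegative")
    case_sum = c.groupby("site_id")["cases"].sum()
    py_sum = p.groupby("site_id")["person_years"].sum()
    missing = sorted(set(case_sum.index) - set(py_sum.index))
    if missing:
        raise ValueError(f"no person-years for site(s): {missing}")
    zero = sorted(py_sum.index[py_sum <= 0])
    if zero:
        raise ValueError(f"nonpositive person-years for site(s): {zero}")
    case_sum = case_sum.reindex(py_sum.index, fill_value=0)
    rate = scale * case_sum / py_sum
    rate.name = "rate"
    return rate


def ks_normality(
    values: np.ndarray, alpha: float = 0.05, variant: str = "lilliefors"
) -> tuple[float, bool]:
    """Kolmogorov–Smirnov test of composite normality.

    Mean and sd are estimated from the data, so the default uses the
    Lilliefors correction; ``variant="plain-ks"`` runs the uncorrected
    one-sample KS against N(mean, sd) for compatibility with toolchains
    that do (anti-conservative).

    Returns (p_value, reject) with reject = p < alpha.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("normality test needs at least 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for constant values")
    if variant == "lilliefors":
        _, p = lilliefors(x, dist="norm")
    elif variant == "plain-ks":
        from scipy import stats

        _, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(p), bool(p < alpha)


def prepare_response(
    rates: pd.Series,
    alpha: float = 0.05,
    transform: str = "auto",
    variant: str = "lilliefors",
    zero_policy: str = "error",
) -> ResponseVector:
    """Build the regression response, applying the log10 gate.

    ``transform="auto"`` runs the normality test and log10-transforms the
    rates when normality is rejected at ``alpha``; "always"/"never" force
    the decision. A zero pooled rate under log10 is an error unless
    ``zero_policy="offset"``, which adds half the smallest nonzero rate
    before the log (the pooling over years exists precisely to avoid
    zeros, so a silent offset would hide data problems).
    """
    values = np.asarray(rates, dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("rates must be finite and nonnegative")
    ks_p, reject = ks_normality(values, alpha=alpha, variant=variant)
    if transform == "auto":
        do_log = reject
    elif transform in ("always", "never"):
        do_log = transform == "always"
    else:
        raise ValueError(f"unknown transform policy {transform!r}")
    if do_log:
        if (values == 0).any():
            if zero_policy == "offset":
                offset = 0.5 * values[values > 0].min()
                values = values + offset
            else:
                raise ValueError(
                    "log10 transform requested but some pooled rates are 0; "
                    "pool over more years or pass zero_policy='offset'"
                )
        values = np.log10(values)
    return ResponseVector(
        site_ids=list(rates.index),
        values=values,
        transform="log10" if do_log else "none",
        ks_p=ks_p,
    )
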