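"""Descriptive burden metrics: ASR, EAPC, risk attribution, SDI quintiles.

The age-standardized rate (ASR) is the standard-population-weighted mean of
age-specific rates, reported per 100,000 person-years:

    ASR = (sum_i a_i w_i / sum_i w_i) * 100000

with a_i the age-specific rate (per person-year) of age group i and w_i the
standard-population weight.  The estimated annual percentage change (EAPC)
summarizes a rate series by ordinary least squares of ln(ASR) on calendar
year: EAPC = 100 * (exp(beta) - 1), with the 95% CI obtained by the same
transform of the slope's normal interval.  Attributable burden applies a
population attributable fraction (PAF) multiplicatively to a total burden.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gbd_io import StandardPopulation
from .lexis import LexisGrid

__all__ = [
    "EAPCResult",
    "compute_asr",
    "asr_series",
    "compute_eapc",
    "attributable_burden",
    "attributable_table",
    "stratify_by_sdi",
    "crude_rate",
    "SDI_QUINTILES",
]

SDI_QUINTILES = ["low", "medium-low", "medium", "medium-high", "high"]


def _weights_array(weights: StandardPopulation | Sequence[float], n: int) -> np.ndarray:
    if isinstance(weights, StandardPopulation):
        w = weights.weights
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have {w.size} age groups, rates have {n}")
    return w


def compute_asr(
    age_specific_rates: Sequence[float],
    weights: StandardPopulation | Sequence[float],
) -> float:
    """Age-standardized rate per 100,000 from per-person-year rates.

    ``weights`` may be a :class:`StandardPopulation` (on the same age groups,
    in order) or a bare array; the scale of the weights is irrelevant.
    """
    a = np.asarray(age_specific_rates, dtype=float)
    if a.ndim != 1:
        raise ValueError("age-specific rates must be a 1-d vector")
    if np.any(a < 0) or np.any(~np.isfinite(a)):
        raise ValueError("age-specific rates must be finite and nonnegative")
    w = _weights_array(weights, a.size)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("standard-population weights must sum to a positive value")
    return float((a @ w) / wsum * 1e5)


def asr_series(grid: LexisGrid, weights: StandardPopulation | Sequence[float]) -> pd.DataFrame:
    """Per-year ASR of a Lexis grid's observed rates; columns (year, asr)."""
    if isinstance(weights, StandardPopulation) and weights.age_groups != grid.age_groups:
        weights = weights.collapse_to(grid.age_groups)
    rates = grid.rates()
    out = [compute_asr(rates[:, j], weights) for j in range(grid.T)]
    return pd.DataFrame({"year": grid.years, "asr": out})


@dataclasses.dataclass(frozen=True)
class EAPCResult:
    """EAPC in percent per year with its 95% CI and the underlying log-linear slope."""

    eapc: float
    ci_lower: float
    ci_upper: float
    slope: float
    slope_se: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.eapc <= self.ci_upper):
            raise ValueError("EAPC must lie inside its confidence interval")


def compute_eapc(series: pd.DataFrame | Mapping[str, Sequence[float]]) -> EAPCResult:
    """EAPC from an ASR series with columns/keys ``year`` and ``asr``.

    Fits ln(asr) = a + beta * year by OLS; EAPC = 100(e^beta - 1) and the CI
    is 100(e^(beta +/- 1.96 SE) - 1).  Requires >= 3 years, all asr > 0.
    """
    df = pd.DataFrame(series)
    if len(df) < 3:
        raise ValueError("EAPC needs at least 3 yearly points")
    year = df["year"].to_numpy(dtype=float)
    asr = df["asr"].to_numpy(dtype=float)
    if np.any(asr <= 0):
        raise ValueError("EAPC is undefined for nonpositive ASR values")
    X = sm.add_constant(year)
    fit = sm.OLS(np.log(asr), X).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    z = 1.959963984540054  # Phi^{-1}(0.975)
    return EAPCResult(
        eapc=100.0 * (np.exp(beta) - 1.0),
        ci_lower=100.0 * (np.exp(beta - z * se) - 1.0),
        ci_upper=100.0 * (np.exp(beta + z * se) - 1.0),
        slope=beta,
        slope_se=se,
    )


def attributable_burden(total, paf):
    """Burden attributable to a risk factor: paf * total (elementwise)."""
    total = np.asarray(total, dtype=float)
    paf = np.asarray(paf, dtype=float)
    if np.any((paf < 0) | (paf > 1)):
        raise ValueError("PAF values must lie in [0, 1]")
    if np.any(total < 0):
        raise ValueError("total burden must be nonnegative")
    out = paf * total
    return float(out) if out.ndim == 0 else out


def attributable_table(
    burden: pd.DataFrame,
    paf: pd.DataFrame,
    on: Sequence[str] = ("risk", "measure", "location", "sex", "age_group", "year", "metric"),
) -> pd.DataFrame:
    """Join PAFs to burden records at their finest common stratum.

    ``burden`` needs the join keys (minus "risk") plus a ``value`` column;
    ``paf`` needs the join keys plus a ``paf`` column.  Returns the joined
    frame with an ``attributable`` column; aggregation across strata, if
    wanted, happens after this join (PAFs are not additive across strata).
    """
    keys = [k for k in on if k in burden.columns and k in paf.columns]
    if not keys:
        raise ValueError("no common join keys between burden and PAF tables")
    merged = burden.merge(paf, on=keys, how="inner")
    merged["attributable"] = attributable_burden(
        merged["value"].to_numpy(), merged["paf"].to_numpy()
    )
    return merged


def stratify_by_sdi(
    locations: Mapping[str, float],
    cutpoints: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
) -> dict[str, str]:
    """Assign SDI quintile labels (low ... high) to locations by rank.

    Locations are ranked by SDI (ties broken by location label, so the
    assignment is deterministic); cutpoints are rank fractions delimiting
    the five classes, equal-mass by default.
    """
    vals = np.asarray(list(locations.values()), dtype=float)
    if np.any((vals < 0) | (vals > 1)) or np.any(~np.isfinite(vals)):
        raise ValueError("SDI values must lie in [0, 1]")
    cut = np.asarray(cutpoints, dtype=float)
    if cut.shape != (4,) or np.any(np.diff(cut) <= 0):
        raise ValueError("cutpoints must be 4 increasing rank fractions")
    ordered = sorted(locations.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(ordered)
    out: dict[str, str] = {}
    for i, (loc, _) in enumerate(ordered):
        frac = (i + 1) / n
        q = int(np.searchsorted(cut, frac, side="left"))
        out[loc] = SDI_QUINTILES[q]
    return out


def crude_rate(counts: float, person_years: float) -> float:
    """Crude rate per 100,000: 1e5 * counts / person-years."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    if counts < 0:
        raise ValueError("counts must be nonnegative")
    return 1e5 * counts / person_years
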