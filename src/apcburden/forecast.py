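"""Projection of fitted APC models over a future horizon.

Each posterior sample carries its own random-walk precisions; the period
effect (and the cohort effect, for the new cohorts that enter the grid with
future periods) is extrapolated per sample by continuing its random walk —
order as fitted, innovation standard deviation taken from that sample's
hyperparameter draw — while age effects are held fixed.  Covariates follow
their scenario rule ("hold" the last observed value, or "linear"
continuation of the observed trend) and stay centered at the observed-year
mean.  Age-specific rate samples exp(eta) are then weighted into
age-standardized rates, summarized by the 2.5/50/97.5 percentiles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .gbd_io import StandardPopulation, read_standard_population
from .metrics import compute_asr
from .model import APCFit

__all__ = ["ForecastResult", "covariate_design", "forecast"]


def covariate_design(
    years: np.ndarray,
    values: np.ndarray,
    rule: str,
    horizon: int,
) -> np.ndarray:
    """Extend an observed covariate series over ``horizon`` future years.

    ``rule="hold"`` repeats the last observed value; ``rule="linear"``
    continues the OLS line through the observed series.  Returns the full
    series (observed then future), uncentered; centering to the
    observed-year mean happens where the series enters the predictor.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape or years.ndim != 1:
        raise ValueError("years and values must be matching 1-d arrays")
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if rule == "hold":
        future = np.full(horizon, values[-1])
    elif rule == "linear":
        coef = np.polyfit(years, values, 1)
        future_years = years[-1] + 1 + np.arange(horizon)
        future = np.polyval(coef, future_years)
    else:
        raise ValueError(f"unknown covariate scenario rule {rule!r}")
    return np.concatenate([values, future])


def _extend_rw(paths: np.ndarray, order: int, sd: np.ndarray, innov: np.ndarray) -> np.ndarray:
    """Continue RW(order) sample paths (S, L) by innov.shape[1] steps."""
    S, L = paths.shape
    H = innov.shape[1]
    out = np.concatenate([paths, np.zeros((S, H))], axis=1)
    for h in range(H):
        j = L + h
        if order == 1:
            drift = out[:, j - 1]
        else:
            drift = 2.0 * out[:, j - 1] - out[:, j - 2]
        out[:, j] = drift + sd * innov[:, h]
    return out


@dataclasses.dataclass
class ForecastResult:
    """Per-sample future age-specific rates plus ASR summaries with 95% UI."""

    years: np.ndarray
    rate_samples: np.ndarray  # (S, A, H) rates per person-year
    asr_samples: np.ndarray  # (S, H) per 100,000
    summary: pd.DataFrame  # columns: year, asr, lower, upper

    def __post_init__(self) -> None:
        if np.any(self.rate_samples <= 0):
            raise ValueError("forecast rates must be positive")
        bad = ~(
            (self.summary["lower"] <= self.summary["asr"])
            & (self.summary["asr"] <= self.summary["upper"])
        )
        if bad.any():
            raise ValueError("forecast interval endpoints out of order")


def forecast(
    fit: APCFit,
    horizon: int,
    covariate_scenario: dict[str, str] | None = None,
    standard_population: StandardPopulation | None = None,
) -> ForecastResult:
    """Project the fitted model ``horizon`` years past the data.

    ``covariate_scenario`` overrides each covariate's extension rule by
    name.  ``standard_population`` supplies the ASR weights (builtin world
    standard, collapsed to the grid's age groups, when omitted).  With
    ``horizon=0`` the last fitted year's summaries are returned unchanged.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    grid = fit.grid
    spec = fit.spec
    if standard_population is None:
        standard_population = read_standard_population("world_standard")
    if standard_population.age_groups != grid.age_groups:
        standard_population = standard_population.collapse_to(grid.age_groups)
    w = standard_population.weights
    S, A, T = fit.eta.shape

    if horizon == 0:
        rates = np.exp(fit.eta[:, :, -1:])
        asr = 1e5 * (rates[:, :, 0] @ w) / w.sum()
        summary = pd.DataFrame(
            {
                "year": [int(grid.years[-1])],
                "asr": [float(np.median(asr))],
                "lower": [float(np.quantile(asr, 0.025))],
                "upper": [float(np.quantile(asr, 0.975))],
            }
        )
        return ForecastResult(
            years=grid.years[-1:].copy(),
            rate_samples=rates,
            asr_samples=asr[:, None],
            summary=summary,
        )

    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(7,)))
    per_ext = _extend_rw(
        fit.period,
        spec.rw_order_period,
        fit.sigma_period,
        rng.standard_normal((S, horizon)),
    )
    coh_ext = _extend_rw(
        fit.cohort,
        spec.rw_order_cohort,
        fit.sigma_cohort,
        rng.standard_normal((S, horizon)),
    )

    cov_future = np.zeros((S, horizon))
    for k, cov in enumerate(spec.covariates):
        rule = cov.scenario
        if covariate_scenario and cov.name in covariate_scenario:
            rule = covariate_scenario[cov.name]
        x_obs = cov.aligned(grid.years)
        full = covariate_design(grid.years, x_obs, rule, horizon)
        centered_future = full[T:] - x_obs.mean()
        cov_future += fit.delta[:, k : k + 1] * centered_future[None, :]

    M = grid.age_width
    ages = np.arange(A)
    future_years = grid.years[-1] + 1 + np.arange(horizon)
    eta_f = np.empty((S, A, horizon))
    for h in range(horizon):
        t = T + h
        cidx = M * (A - 1 - ages) + t
        eta_f[:, :, h] = (
            fit.mu[:, None]
            + fit.age
            + per_ext[:, t][:, None]
            + coh_ext[:, cidx]
            + cov_future[:, h][:, None]
        )
    rates = np.exp(eta_f)
    asr = 1e5 * np.einsum("sah,a->sh", rates, w) / w.sum()
    med = np.median(asr, axis=0)
    lo = np.quantile(asr, 0.025, axis=0)
    hi = np.quantile(asr, 0.975, axis=0)
    summary = pd.DataFrame(
        {"year": future_years.astype(int), "asr": med, "lower": lo, "upper": hi}
    )
    # consistency with the scalar definition on the weight scale
    assert np.isclose(asr[0, 0], compute_asr(rates[0, :, 0], standard_population))
    return ForecastResult(
        years=future_years,
        rate_samples=rates,
        asr_samples=asr,
        summary=summary,
    )
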