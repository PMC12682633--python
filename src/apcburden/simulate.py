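"""Synthetic GBD-like burden data with known ground truth.

Counts are drawn on an age x year Lexis grid from a Poisson law whose
log-rate is an additive age/period/cohort surface plus optional log-linear
covariate effects, over a deterministic population pyramid; the result is
emitted both as an in-memory :class:`~apcburden.lexis.LexisGrid` and as a
GBD-dialect file (consistent number and rate rows), with a JSON sidecar
recording the generating truth.

The default shape mirrors the study grid: 18 five-year age groups (0-4
through 85 plus) over 32 annual periods (1990-2021).  The default log-rate
age curve is quadratic, rising roughly half a log unit per five-year group
before flattening, with the intercept placed so that expected total events
over the default population are of order 3e5 — the scale of a common
cancer in a large population — without asserting any real-world figure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .gbd_io import BurdenTable, PopulationGrid, write_burden_table
from .lexis import LexisGrid, n_cohorts
from .model import APCModelSpec, Covariate

__all__ = [
    "SyntheticTruth",
    "default_age_groups",
    "generate_population",
    "generate_apc_truth",
    "generate_model_truth",
    "generate_dataset",
]

SCENARIOS = ("age_only", "drift", "full_apc", "covariate")


def default_age_groups(A: int = 18, width: int = 5) -> list[str]:
    """Labels '0 to 4' ... with a terminal open group, youngest first."""
    labels = [f"{i * width} to {(i + 1) * width - 1}" for i in range(A - 1)]
    labels.append(f"{(A - 1) * width} plus")
    return labels


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth APC surface and parameters behind a generated dataset.

    The stored curves satisfy the same identifiability constraints the
    model imposes (sum-to-zero effects, zero linear trend in the cohort
    curve); components removed by constraining are folded back into the
    intercept and the period curve so that ``eta()`` is exactly the surface
    that was designed.
    """

    scenario: str
    mu: float
    age: np.ndarray
    period: np.ndarray
    cohort: np.ndarray
    drift: float
    age_groups: list[str]
    years: np.ndarray
    age_width: int
    seed: int
    covariates: tuple[Covariate, ...] = ()
    delta: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))

    @property
    def A(self) -> int:
        return self.age.size

    @property
    def T(self) -> int:
        return self.period.size

    def eta(self) -> np.ndarray:
        """True log-rate surface (A, T) including drift and covariate terms."""
        A, T, M = self.A, self.T, self.age_width
        a = np.arange(A)[:, None]
        t = np.arange(T)[None, :]
        cidx = M * (A - 1 - a) + t
        tt = np.arange(T) - (T - 1) / 2.0
        eta = self.mu + self.age[:, None] + (self.period + self.drift * tt)[None, :]
        eta = eta + self.cohort[cidx]
        for k, cov in enumerate(self.covariates):
            x = cov.aligned(self.years)
            eta = eta + self.delta[k] * (x - x.mean())[None, :]
        return eta

    def model_spec(self, **overrides) -> APCModelSpec:
        """An APCModelSpec whose covariates match the generating truth."""
        kwargs = {"covariates": self.covariates}
        kwargs.update(overrides)
        return APCModelSpec(**kwargs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "mu": self.mu,
            "age": self.age.tolist(),
            "period": self.period.tolist(),
            "cohort": self.cohort.tolist(),
            "drift": self.drift,
            "age_groups": self.age_groups,
            "years": self.years.tolist(),
            "age_width": self.age_width,
            "seed": self.seed,
            "delta": self.delta.tolist(),
            "covariates": [
                {
                    "name": c.name,
                    "years": list(c.years),
                    "values": list(c.values),
                    "scenario": c.scenario,
                }
                for c in self.covariates
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            scenario=d["scenario"],
            mu=d["mu"],
            age=np.array(d["age"]),
            period=np.array(d["period"]),
            cohort=np.array(d["cohort"]),
            drift=d["drift"],
            age_groups=d["age_groups"],
            years=np.array(d["years"], dtype=int),
            age_width=d["age_width"],
            seed=d["seed"],
            covariates=tuple(
                Covariate.from_series(c["name"], c["years"], c["values"], c["scenario"])
                for c in d["covariates"]
            ),
            delta=np.array(d["delta"]),
        )


def generate_population(
    A: int = 18,
    T: int = 32,
    base_size: float = 1e6,
    growth_rate: float = 0.005,
    pyramid_shape: str = "declining",
    seed: int | None = None,
    start_year: int = 1990,
    age_width: int = 5,
) -> PopulationGrid:
    """Deterministic person-years n[a, t] = base_size * shape(a) * (1+g)^t.

    ``pyramid_shape="declining"`` is an exponential pyramid,
    shape(a) = exp(-0.09 a) (oldest group about a fifth of the youngest);
    ``"uniform"`` gives equal person-years across ages.  ``seed`` is
    accepted for API uniformity but unused: the population is deterministic.
    """
    if base_size <= 0:
        raise ValueError("base_size must be positive")
    if pyramid_shape == "uniform":
        shape = np.ones(A)
    elif pyramid_shape == "declining":
        shape = np.exp(-0.09 * np.arange(A))
    else:
        raise ValueError(f"unknown pyramid shape {pyramid_shape!r}")
    growth = (1.0 + growth_rate) ** np.arange(T)
    n = base_size * shape[:, None] * growth[None, :]
    return PopulationGrid(
        person_years=n,
        age_groups=default_age_groups(A, age_width),
        years=start_year + np.arange(T),
    )


def _constrain(curve: np.ndarray, detrend: bool = False) -> tuple[np.ndarray, float, float]:
    """Center (and optionally detrend) a curve; returns (curve, level, slope)."""
    idx = np.arange(curve.size) - (curve.size - 1) / 2.0
    slope = 0.0
    if detrend:
        slope = float(idx @ curve / (idx @ idx))
        curve = curve - slope * idx
    level = float(curve.mean())
    return curve - level, level, slope


def generate_apc_truth(
    A: int = 18,
    T: int = 32,
    scenario: str = "full_apc",
    seed: int = 0,
    drift: float = 0.01,
    mu: float = -8.1,
    cohort_amplitude: float = 0.15,
    cohort_wavelength: float = 60.0,
    delta: float = 1.2,
    start_year: int = 1990,
    age_width: int = 5,
) -> SyntheticTruth:
    """Ground-truth APC curves for one of the named scenarios.

    Scenarios nest: ``age_only`` is a quadratic log-rate age curve with no
    period or cohort structure; ``drift`` adds a linear period trend of
    ``drift`` per year; ``full_apc`` adds a smooth sinusoidal cohort wave;
    ``covariate`` further adds a declining exposure series with log-linear
    coefficient ``delta``.  Curves are returned in constrained form
    (sum-to-zero, cohort detrended) with removed components folded into the
    intercept, drift and period so the designed surface is unchanged.
    Deterministic given the arguments; ``seed`` is recorded for downstream
    count generation.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    C = n_cohorts(A, T, age_width)
    z = np.arange(A) - (A - 1) / 2.0
    age_curve = 0.45 * z - 0.012 * z**2
    period_curve = np.zeros(T)
    cohort_curve = np.zeros(C)
    use_drift = drift if scenario in ("drift", "full_apc", "covariate") else 0.0
    if scenario in ("full_apc", "covariate"):
        c = np.arange(C) - (C - 1) / 2.0
        cohort_curve = cohort_amplitude * np.sin(2.0 * np.pi * c / cohort_wavelength)

    age_curve, a_level, _ = _constrain(age_curve)
    period_curve, p_level, _ = _constrain(period_curve)
    cohort_curve, c_level, c_slope = _constrain(cohort_curve, detrend=True)
    # redistribute what constraining removed so eta() is the designed surface:
    # a cohort linear trend s*c with c = M(A-1-a)+t splits into an age-linear
    # part (absorbed exactly by re-centering since age_curve keeps its shape)
    # and a period drift s per year.
    mu_adj = mu + a_level + p_level + c_level
    age_adj = age_curve + c_slope * age_width * (np.arange(A)[::-1] - (A - 1) / 2.0)
    age_adj, extra_level, _ = _constrain(age_adj)
    mu_adj += extra_level
    drift_adj = use_drift + c_slope

    covariates: tuple[Covariate, ...] = ()
    delta_arr = np.zeros(0)
    years = start_year + np.arange(T)
    if scenario == "covariate":
        x = 0.40 - 0.005 * np.arange(T)  # declining exposure prevalence
        covariates = (Covariate.from_series("exposure", years, x, scenario="hold"),)
        delta_arr = np.array([delta])

    return SyntheticTruth(
        scenario=scenario,
        mu=mu_adj,
        age=age_adj,
        period=period_curve,
        cohort=cohort_curve,
        drift=drift_adj,
        age_groups=default_age_groups(A, age_width),
        years=years,
        age_width=age_width,
        seed=seed,
        covariates=covariates,
        delta=delta_arr,
    )


def generate_model_truth(
    A: int = 18,
    T: int = 32,
    seed: int = 0,
    sigma_period: float = 0.015,
    sigma_cohort: float = 0.003,
    drift: float = 0.01,
    mu: float = -8.1,
    rw_order: int = 2,
    start_year: int = 1990,
    age_width: int = 5,
) -> SyntheticTruth:
    """A truth drawn from the model class itself: random-walk period and
    cohort effects on top of the standard quadratic age curve.

    Unlike the named deterministic scenarios, the period and cohort curves
    here are genuine RW(``rw_order``) sample paths with the given innovation
    standard deviations, then constrained (sum-to-zero, cohort and period
    detrended, removed components folded into intercept/age/drift).  This is
    the right ground truth for calibration experiments, where data must come
    from the same stochastic family the model assumes.  Default innovation
    scales are set so realized detrended curve amplitudes are ~0.1 (period)
    and ~0.15 (cohort) on the log scale, matching the deterministic
    scenarios; under an order-2 walk the path scale grows like sd * m^{3/2},
    so the per-step scales are small.
    """
    rng = np.random.default_rng(seed)
    C = n_cohorts(A, T, age_width)

    def rw_path(m: int, sd: float) -> np.ndarray:
        innov = sd * rng.standard_normal(m)
        path = np.cumsum(innov)
        if rw_order == 2:
            path = np.cumsum(path)
        return path

    z = np.arange(A) - (A - 1) / 2.0
    age_curve = 0.45 * z - 0.012 * z**2
    period_curve = rw_path(T, sigma_period)
    cohort_curve = rw_path(C, sigma_cohort)

    age_curve, a_level, _ = _constrain(age_curve)
    period_curve, p_level, p_slope = _constrain(period_curve, detrend=True)
    cohort_curve, c_level, c_slope = _constrain(cohort_curve, detrend=True)
    mu_adj = mu + a_level + p_level + c_level
    age_adj = age_curve + c_slope * age_width * (np.arange(A)[::-1] - (A - 1) / 2.0)
    age_adj, extra_level, _ = _constrain(age_adj)
    mu_adj += extra_level
    drift_adj = drift + p_slope + c_slope
    return SyntheticTruth(
        scenario="model_rw",
        mu=mu_adj,
        age=age_adj,
        period=period_curve,
        cohort=cohort_curve,
        drift=drift_adj,
        age_groups=default_age_groups(A, age_width),
        years=start_year + np.arange(T),
        age_width=age_width,
        seed=seed,
    )


def generate_dataset(
    truth: SyntheticTruth,
    population: PopulationGrid,
    seed: int | None = None,
    out_path: str | Path | None = None,
    measure: str = "incidence",
    location: str = "Synthetica",
    sex: str = "both",
    cause: str = "colon and rectum cancer",
) -> tuple[LexisGrid, BurdenTable]:
    """Draw Poisson counts from the truth and emit grid + GBD-dialect table.

    ``seed`` defaults to ``truth.seed``.  When ``out_path`` is given the
    table is written there (byte-deterministic) together with a
    ``<out_path>.truth.json`` sidecar.  Raises when any cell mean exceeds
    1e12 (overflow-scale rates).
    """
    if population.age_groups != truth.age_groups or not np.array_equal(
        population.years, truth.years
    ):
        raise ValueError("population grid and truth must share age groups and years")
    eta = truth.eta()
    mean = population.person_years * np.exp(eta)
    if np.any(mean > 1e12):
        raise ValueError("cell means exceed 1e12; rates are at overflow scale")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    y = rng.poisson(mean).astype(float)
    grid = LexisGrid(
        counts=y,
        person_years=population.person_years,
        age_groups=list(truth.age_groups),
        years=truth.years,
        age_width=truth.age_width,
    )
    rows = []
    for i, g in enumerate(truth.age_groups):
        for j, yr in enumerate(truth.years):
            count = y[i, j]
            rate = 1e5 * count / population.person_years[i, j]
            for metric, val in (("number", count), ("rate", rate)):
                rows.append(
                    (measure, location, sex, g, cause, "", metric, int(yr), val, val, val)
                )
    table = BurdenTable(
        pd.DataFrame(
            rows,
            columns=[
                "measure",
                "location",
                "sex",
                "age",
                "cause",
                "rei",
                "metric",
                "year",
                "val",
                "upper",
                "lower",
            ],
        )
    )
    if out_path is not None:
        out_path = Path(out_path)
        write_burden_table(table, out_path)
        truth.to_json(out_path.with_suffix(out_path.suffix + ".truth.json"))
    return grid, table
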