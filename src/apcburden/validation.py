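"""Back-testing and model criticism for APC forecasts.

``backtest`` refits the model on a training window, projects the held-out
years, and scores the posterior-predictive distribution of observed
age-specific rates against what was actually observed: MAE and RMSE of the
predictive median, the mean continuous ranked probability score (CRPS,
ensemble estimator), and the fraction of cells whose observation falls in
the central 95% predictive interval.  Scores are computed on the log-rate
scale by default (the model is linear there), with a half-count continuity
correction log((y + 1/2) / n) applied jointly to predicted and observed
cells so that sparse cells with zero counts remain scoreable — the
correction is monotone in the count, so interval coverage is unaffected.
``scale="rate"`` switches to the natural scale.

Model criticism uses the deviance information criterion (DIC), the
Watanabe-Akaike information criterion (WAIC) and the sum of log conditional
predictive ordinates (CPO, harmonic-mean estimator with an instability
flag).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .lexis import LexisGrid
from .model import APCFit, APCModelSpec, fit_apc
from .forecast import forecast
from .gbd_io import StandardPopulation

__all__ = [
    "ValidationReport",
    "crps_ensemble",
    "coverage",
    "score_cells",
    "information_criteria",
    "backtest",
]


def crps_ensemble(samples: np.ndarray, y: float) -> float:
    """CRPS of an ensemble forecast: mean|X-y| - (1/(2 S^2)) sum_ij |X_i-X_j|."""
    x = np.sort(np.asarray(samples, dtype=float))
    S = x.size
    if S < 2:
        raise ValueError("CRPS ensemble estimator needs at least 2 samples")
    term1 = np.mean(np.abs(x - y))
    # sum_ij |x_i - x_j| = 2 * sum_i (2i - S - 1) x_(i), i = 1..S ascending
    i = np.arange(1, S + 1)
    pairwise = 2.0 * np.sum((2 * i - S - 1) * x)
    return float(term1 - pairwise / (2.0 * S * S))


def coverage(intervals: np.ndarray, y: np.ndarray) -> float:
    """Fraction of cells with lo <= y <= hi; boundaries count as covered."""
    arr = np.asarray(intervals, dtype=float)
    lo, hi = arr[..., 0], arr[..., 1]
    if np.any(lo > hi):
        raise ValueError("interval lower bounds must not exceed upper bounds")
    y = np.asarray(y, dtype=float)
    return float(np.mean((lo <= y) & (y <= hi)))


def score_cells(
    pred_samples: np.ndarray,
    observed: np.ndarray,
    level: float = 0.95,
) -> dict[str, float]:
    """Score a (S, ncell) predictive ensemble against ncell observations.

    Returns mae/rmse of the per-cell predictive median, mean CRPS, and
    central-interval coverage at ``level``.
    """
    pred = np.asarray(pred_samples, dtype=float)
    obs = np.asarray(observed, dtype=float).ravel()
    if pred.ndim != 2 or pred.shape[1] != obs.size:
        raise ValueError("pred_samples must be (S, ncell) matching observed")
    med = np.median(pred, axis=0)
    err = med - obs
    q = (1.0 - level) / 2.0
    lo = np.quantile(pred, q, axis=0)
    hi = np.quantile(pred, 1.0 - q, axis=0)
    crps = np.array([crps_ensemble(pred[:, j], obs[j]) for j in range(obs.size)])
    return {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "crps_mean": float(np.mean(crps)),
        "coverage95": coverage(np.stack([lo, hi], axis=-1), obs),
    }


def information_criteria(fit: APCFit, grid: LexisGrid | None = None) -> dict[str, float]:
    """DIC, WAIC and the summed log-CPO of a fit on its (or another) grid.

    DIC uses the posterior-mean linear predictor as the plug-in:
    DIC = -2 ln p(y|eta_bar) + 2 p_D, p_D = 2[ln p(y|eta_bar) - E ln p(y|eta)].
    WAIC = -2[sum_i ln E p(y_i|eta) - sum_i Var ln p(y_i|eta)].
    CPO_i is the harmonic mean of per-sample likelihoods; ``cpo_unstable``
    counts cells whose harmonic-mean weights have coefficient of variation
    above 10.
    """
    if grid is None:
        grid = fit.grid
    ll = fit.loglik_matrix()  # (S, N)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite per-cell log-likelihoods")
    y = grid.counts.ravel()
    n = grid.person_years.ravel()
    eta_bar = fit.eta.reshape(fit.sample_count, -1).mean(axis=0)
    m_bar = n * np.exp(eta_bar)
    ll_bar = float(np.sum(y * np.log(m_bar) - m_bar - gammaln(y + 1.0)))
    mean_ll = float(np.mean(np.sum(ll, axis=1)))
    p_d = 2.0 * (ll_bar - mean_ll)
    dic = -2.0 * ll_bar + 2.0 * p_d

    # stabilized log-mean-exp over samples per cell
    mx = ll.max(axis=0)
    lppd = float(np.sum(mx + np.log(np.mean(np.exp(ll - mx), axis=0))))
    p_waic = float(np.sum(np.var(ll, axis=0)))
    waic = -2.0 * (lppd - p_waic)

    # harmonic-mean CPO: 1 / mean(exp(-ll)) per cell
    neg = -ll
    mxn = neg.max(axis=0)
    log_mean_inv = mxn + np.log(np.mean(np.exp(neg - mxn), axis=0))
    cpo_log_sum = float(np.sum(-log_mean_inv))
    w = np.exp(neg - mxn)
    cv = np.std(w, axis=0) / np.mean(w, axis=0)
    return {
        "dic": dic,
        "p_d": p_d,
        "waic": waic,
        "p_waic": p_waic,
        "cpo_log_sum": cpo_log_sum,
        "cpo_unstable": int(np.sum(cv > 10.0)),
    }


@dataclasses.dataclass
class ValidationReport:
    """Back-test scores, model criticism, and the split that produced them."""

    train_years: tuple[int, int]
    test_years: tuple[int, int]
    scale: str
    scores: dict[str, float]
    criticism: dict[str, float]

    def __post_init__(self) -> None:
        for k in ("mae", "rmse", "crps_mean"):
            if self.scores[k] < 0:
                raise ValueError(f"{k} must be nonnegative")
        if not (0.0 <= self.scores["coverage95"] <= 1.0):
            raise ValueError("coverage must be a fraction in [0, 1]")

    def to_frame(self, stratum: str = "all") -> pd.DataFrame:
        rows = [(stratum, k, v) for k, v in {**self.scores, **self.criticism}.items()]
        return pd.DataFrame(rows, columns=["stratum", "metric", "value"])

    def summary(self) -> str:
        lines = [
            f"back-test: trained {self.train_years[0]}-{self.train_years[1]}, "
            f"scored {self.test_years[0]}-{self.test_years[1]} ({self.scale} scale)",
            f"  MAE {self.scores['mae']:.4g}   RMSE {self.scores['rmse']:.4g}   "
            f"CRPS {self.scores['crps_mean']:.4g}   "
            f"95% coverage {self.scores['coverage95']:.3f}",
            f"  DIC {self.criticism['dic']:.4g}   WAIC {self.criticism['waic']:.4g}   "
            f"sum log CPO {self.criticism['cpo_log_sum']:.4g}"
            + ("  [CPO unstable]" if self.criticism["cpo_unstable"] else ""),
        ]
        return "\n".join(lines)


def backtest(
    grid: LexisGrid,
    spec: APCModelSpec,
    split_year: int,
    scale: str = "log",
    standard_population: StandardPopulation | None = None,
    include_sampling_noise: bool = True,
) -> ValidationReport:
    """Train up to ``split_year``, predict the remaining years, score them.

    The predictive ensemble is posterior-predictive by default: each
    posterior rate sample is combined with Poisson observation noise at the
    held-out exposures, so the scored distribution is that of the observable
    rate y/n.  Deterministic given ``spec.seed``.
    """
    years = grid.years
    n_train = int(np.sum(years <= split_year))
    n_test = int(np.sum(years > split_year))
    if n_train < 4 or n_test < 1:
        raise ValueError(
            f"degenerate split at {split_year}: {n_train} training and {n_test} test periods"
        )
    if scale not in ("log", "rate"):
        raise ValueError("scale must be 'log' or 'rate'")
    train = grid.slice_years(int(years[0]), split_year)
    test = grid.slice_years(split_year + 1, int(years[-1]))
    fit = fit_apc(train, spec)
    fc = forecast(fit, horizon=n_test, standard_population=standard_population)
    S = fc.rate_samples.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(11,)))
    n_test_py = test.person_years
    if include_sampling_noise:
        counts = rng.poisson(fc.rate_samples * n_test_py[None, :, :])
        pred_rate = counts / n_test_py[None, :, :]
    else:
        pred_rate = fc.rate_samples
    obs_rate = test.rates()
    if scale == "log":
        # half-count continuity correction, applied jointly (monotone in y)
        shift = 0.5 / n_test_py[None, :, :]
        pred = np.log(pred_rate + shift).reshape(S, -1)
        obs = np.log(obs_rate + shift[0]).ravel()
    else:
        pred = pred_rate.reshape(S, -1)
        obs = obs_rate.ravel()
    scores = score_cells(pred, obs)
    crit = information_criteria(fit)
    return ValidationReport(
        train_years=(int(train.years[0]), int(train.years[-1])),
        test_years=(int(test.years[0]), int(test.years[-1])),
        scale=scale,
        scores=scores,
        criticism=crit,
    )
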