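"""Bayesian age-period-cohort model: Poisson counts on a Lexis grid.

The linear predictor of the log rate in cell (a, t) is

    eta[a, t] = mu + alpha_a + beta_t + gamma_c(a,t) + sum_k delta_k x_k(t)

with counts y[a, t] ~ Poisson(n[a, t] * exp(eta[a, t])) (optionally
negative-binomial when overdispersion is switched on).  Age, period and
cohort effects are intrinsic random walks (order 1 or 2, default 2) with
penalized-complexity priors on their standard deviations; covariates x_k
are centered over the observed years and enter with log-linear
coefficients delta_k under a weak normal prior (or fixed, if supplied).

Individual APC effects are not identifiable; the model imposes an explicit
constraint scheme (default: sum-to-zero on all three effects plus
zero-linear-trend on the cohort effect, so the common drift is carried by
the period effect) and treats the linear predictor eta — which is invariant
to the choice of valid constraint scheme — as the inferential output.

Inference is empirical-Bayes Laplace in the style of INLA: for each value
of the hyperparameters (log precisions, plus log dispersion when
overdispersed) the latent field is approximated by a Gaussian at its
conditional mode; the hyperparameters are optimized on the resulting
Laplace marginal posterior and then integrated over by sampling from the
Gaussian approximation of their posterior.  ``fit_apc`` returns joint
posterior samples of every latent quantity and is deterministic given the
spec's seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.special import gammaln

from .lexis import LexisGrid, n_cohorts
from .priors import pc_prior_logdensity, pc_prior_rate, rw_log_prior, rw_structure

__all__ = [
    "Covariate",
    "APCModelSpec",
    "APCState",
    "APCFit",
    "APCFitError",
    "poisson_loglik",
    "log_posterior",
    "fit_apc",
]

_THETA_BOUND = 40.0  # |log tau| beyond this is treated as numerically degenerate


class APCFitError(RuntimeError):
    """Model fitting failed; carries a diagnostics dict."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclasses.dataclass(frozen=True)
class Covariate:
    """A time-dependent covariate entering the period dimension log-linearly.

    ``years``/``values`` give the observed exposure series (must cover the
    fitted years); ``scenario`` ("hold" or "linear") says how the series is
    extended beyond the data when forecasting; ``coefficient`` fixes the
    log-linear coefficient to a known value instead of estimating it.
    """

    name: str
    years: tuple[int, ...]
    values: tuple[float, ...]
    scenario: str = "hold"
    coefficient: float | None = None

    @classmethod
    def from_series(cls, name, years, values, scenario="hold", coefficient=None):
        return cls(
            name=name,
            years=tuple(int(y) for y in years),
            values=tuple(float(v) for v in values),
            scenario=scenario,
            coefficient=coefficient,
        )

    def aligned(self, years: np.ndarray) -> np.ndarray:
        lookup = dict(zip(self.years, self.values))
        missing = [int(y) for y in years if int(y) not in lookup]
        if missing:
            raise ValueError(f"covariate {self.name!r} lacks values for years {missing}")
        return np.array([lookup[int(y)] for y in years], dtype=float)


@dataclasses.dataclass(frozen=True)
class APCModelSpec:
    """Configuration of the Bayesian APC model.

    Parameters
    ----------
    rw_order_age, rw_order_period, rw_order_cohort
        Random-walk order (1 or 2) of each smooth effect; default 2.
    pc_u, pc_alpha
        PC-prior hyperparameters: P(sigma > pc_u) = pc_alpha for each
        random-walk standard deviation (log-rate scale).
    covariates
        Time-dependent covariates with log-linear coefficients.
    sample_count
        Number of joint posterior draws returned by :func:`fit_apc`.
    overdispersion
        "off" (Poisson) or "on" (negative binomial with estimated
        log-dispersion).
    seed
        Seed for every stochastic step of fitting; same seed, same samples.
    constraints
        "sum_zero" (default) or "corner"; both remove exactly the
        penalty null-space directions, so eta is unaffected by the choice.
    """

    rw_order_age: int = 2
    rw_order_period: int = 2
    rw_order_cohort: int = 2
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    covariates: tuple[Covariate, ...] = ()
    sample_count: int = 1000
    overdispersion: str = "off"
    seed: int = 0
    constraints: str = "sum_zero"
    mu_prior_sd: float = 10.0
    delta_prior_sd: float = 10.0
    theta_points: int = 25

    def __post_init__(self) -> None:
        for o in (self.rw_order_age, self.rw_order_period, self.rw_order_cohort):
            if o not in (1, 2):
                raise ValueError("random-walk orders must be 1 or 2")
        if self.sample_count < 1:
            raise ValueError("sample_count must be >= 1")
        if not (0 < self.pc_alpha < 1) or not (self.pc_u > 0):
            raise ValueError("PC prior needs U > 0 and 0 < alpha < 1")
        if self.overdispersion not in ("off", "on"):
            raise ValueError("overdispersion must be 'off' or 'on'")
        if self.constraints not in ("sum_zero", "corner"):
            raise ValueError("constraints must be 'sum_zero' or 'corner'")


@dataclasses.dataclass
class APCState:
    """A full (unconstrained) point in parameter space, for density evaluation."""

    mu: float
    age: np.ndarray
    period: np.ndarray
    cohort: np.ndarray
    sigma_age: float
    sigma_period: float
    sigma_cohort: float
    delta: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))
    phi: float | None = None


def poisson_loglik(counts: np.ndarray, person_years: np.ndarray, eta: np.ndarray) -> float:
    """Poisson log-likelihood term sum(y * ln(n e^eta) - n e^eta), no factorial."""
    y = np.asarray(counts, dtype=float)
    n = np.asarray(person_years, dtype=float)
    mean = n * np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(mean), 0.0)
    if np.any((y > 0) & (mean == 0)):
        return -np.inf
    return float(np.sum(term - mean))


def _nb_loglik(y, n, eta, phi):
    m = n * np.exp(eta)
    return float(
        np.sum(
            gammaln(y + phi)
            - gammaln(phi)
            - gammaln(y + 1.0)
            + phi * np.log(phi / (phi + m))
            + y * np.log(m / (phi + m))
        )
    )


def _state_eta(state: APCState, grid: LexisGrid, spec: APCModelSpec) -> np.ndarray:
    cidx = grid.cohort_index
    eta = state.mu + state.age[:, None] + state.period[None, :] + state.cohort[cidx]
    for k, cov in enumerate(spec.covariates):
        x = cov.aligned(grid.years)
        x = x - x.mean()
        coef = cov.coefficient if cov.coefficient is not None else state.delta[k]
        eta = eta + coef * x[None, :]
    return eta


def log_posterior(state: APCState, grid: LexisGrid, spec: APCModelSpec) -> float:
    """Exact log-posterior density (up to a constant) at an unconstrained state.

    Sum of the count likelihood, the random-walk log-priors of the age,
    period and cohort effects, the PC prior log-densities of their standard
    deviations, and weak normal priors on the intercept and the free
    covariate coefficients.
    """
    vals = np.concatenate(
        [
            [state.mu, state.sigma_age, state.sigma_period, state.sigma_cohort],
            np.ravel(state.age),
            np.ravel(state.period),
            np.ravel(state.cohort),
            np.ravel(state.delta),
        ]
    )
    if not np.all(np.isfinite(vals)):
        raise ValueError("state contains non-finite values")
    if state.age.size != grid.A or state.period.size != grid.T:
        raise ValueError("state dimensions do not match grid")
    if state.cohort.size != grid.n_cohorts:
        raise ValueError("cohort effect length must equal the number of cohorts")
    eta = _state_eta(state, grid, spec)
    if spec.overdispersion == "on":
        if state.phi is None or state.phi <= 0:
            raise ValueError("overdispersed model needs a positive dispersion phi")
        ll = _nb_loglik(grid.counts, grid.person_years, eta, state.phi)
    else:
        ll = poisson_loglik(grid.counts, grid.person_years, eta)
    lp = ll
    for u, order, sigma in (
        (state.age, spec.rw_order_age, state.sigma_age),
        (state.period, spec.rw_order_period, state.sigma_period),
        (state.cohort, spec.rw_order_cohort, state.sigma_cohort),
    ):
        if sigma <= 0:
            raise ValueError("random-walk standard deviations must be positive")
        lp += rw_log_prior(u, order, 1.0 / sigma**2)
        lp += pc_prior_logdensity(sigma, spec.pc_u, spec.pc_alpha)
    lp += -0.5 * (state.mu / spec.mu_prior_sd) ** 2 - np.log(spec.mu_prior_sd)
    for k, cov in enumerate(spec.covariates):
        if cov.coefficient is None:
            lp += -0.5 * (state.delta[k] / spec.delta_prior_sd) ** 2 - np.log(
                spec.delta_prior_sd
            )
    return float(lp)


# ---------------------------------------------------------------------------
# internal design assembly


def _constraint_basis(m: int, scheme: str, *, cohort: bool = False) -> np.ndarray:
    """Orthonormal basis of the constrained subspace for one effect vector."""
    if scheme == "sum_zero":
        rows = [np.ones(m)]
        if cohort:
            rows.append(np.arange(m) - (m - 1) / 2.0)
    else:  # corner
        rows = [np.eye(m)[0]]
        if cohort:
            rows.append(np.eye(m)[1])
    return sla.null_space(np.vstack(rows))


class _Design:
    """Dense design linking the reduced latent vector to the cell predictor."""

    def __init__(self, grid: LexisGrid, spec: APCModelSpec):
        A, T, C = grid.A, grid.T, grid.n_cohorts
        self.grid, self.spec = grid, spec
        self.Ba = _constraint_basis(A, spec.constraints)
        self.Bt = _constraint_basis(T, spec.constraints)
        self.Bc = _constraint_basis(C, spec.constraints, cohort=True)
        self.K = {
            "age": self.Ba.T @ rw_structure(A, spec.rw_order_age) @ self.Ba,
            "period": self.Bt.T @ rw_structure(T, spec.rw_order_period) @ self.Bt,
            "cohort": self.Bc.T @ rw_structure(C, spec.rw_order_cohort) @ self.Bc,
        }
        self.ranks = np.array(
            [A - spec.rw_order_age, T - spec.rw_order_period, C - spec.rw_order_cohort],
            dtype=float,
        )
        cells_age = np.repeat(np.arange(A), T)
        cells_per = np.tile(np.arange(T), A)
        cells_coh = grid.cohort_index.ravel()
        N = A * T
        cols = [np.ones((N, 1))]
        cols.append(self.Ba[cells_age])
        cols.append(self.Bt[cells_per])
        cols.append(self.Bc[cells_coh])
        self.x_centered: list[np.ndarray] = []
        self.free_cov: list[int] = []
        fixed_offset = np.zeros(N)
        for k, cov in enumerate(spec.covariates):
            x = cov.aligned(grid.years)
            xc = x - x.mean()
            self.x_centered.append(xc)
            if cov.coefficient is None:
                self.free_cov.append(k)
                cols.append(xc[cells_per][:, None])
            else:
                fixed_offset += cov.coefficient * xc[cells_per]
        self.M = np.hstack(cols)
        self.fixed_offset = fixed_offset
        pa, pt, pc = self.Ba.shape[1], self.Bt.shape[1], self.Bc.shape[1]
        self.sl_mu = slice(0, 1)
        self.sl_age = slice(1, 1 + pa)
        self.sl_per = slice(1 + pa, 1 + pa + pt)
        self.sl_coh = slice(1 + pa + pt, 1 + pa + pt + pc)
        self.sl_del = slice(1 + pa + pt + pc, 1 + pa + pt + pc + len(self.free_cov))
        self.p = self.M.shape[1]
        self.y = grid.counts.ravel()
        # exposure folded with the fixed-covariate offset: mean = noff * exp(M x)
        self.noff = grid.person_years.ravel() * np.exp(fixed_offset)

    def prior_precision(self, taus: np.ndarray) -> np.ndarray:
        spec = self.spec
        Q = np.zeros((self.p, self.p))
        Q[0, 0] = 1.0 / spec.mu_prior_sd**2
        Q[self.sl_age, self.sl_age] = taus[0] * self.K["age"]
        Q[self.sl_per, self.sl_per] = taus[1] * self.K["period"]
        Q[self.sl_coh, self.sl_coh] = taus[2] * self.K["cohort"]
        nfree = len(self.free_cov)
        if nfree:
            Q[self.sl_del, self.sl_del] = np.eye(nfree) / spec.delta_prior_sd**2
        return Q

    def lik_terms(self, eta: np.ndarray, phi: float | None):
        """(loglik, d loglik / d eta, -d2 loglik / d eta2) per cell."""
        with np.errstate(over="ignore"):
            m = self.noff * np.exp(eta)
        if not np.all(np.isfinite(m)):
            return -np.inf, None, None
        if phi is None:
            ll = float(np.sum(self.y * eta - m))
            return ll, self.y - m, m
        ll = float(
            np.sum(
                gammaln(self.y + phi)
                - gammaln(phi)
                + phi * np.log(phi / (phi + m))
                + self.y * np.log(m / (phi + m) + 1e-300)
            )
        )
        frac = m / (phi + m)  # in (0, 1), overflow-free
        grad = self.y - (self.y + phi) * frac
        w = (self.y + phi) * frac * (phi / (phi + m))
        return ll, grad, w


def _newton_mode(design: _Design, Q0: np.ndarray, phi, x0: np.ndarray):
    """Maximize loglik(x) - x'Q0x/2; returns (x*, chol(H), f(x*), iters)."""
    x = x0.copy()
    M = design.M
    eta = M @ x
    ll, grad_eta, w = design.lik_terms(eta, phi)
    f = ll - 0.5 * x @ Q0 @ x
    if not np.isfinite(f):
        x = np.zeros_like(x)
        eta = M @ x
        ll, grad_eta, w = design.lik_terms(eta, phi)
        f = ll - 0.5 * x @ Q0 @ x
    L = None
    for it in range(100):
        H = Q0 + (M * w[:, None]).T @ M
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(design.p)
            L = np.linalg.cholesky(H)
        g = M.T @ grad_eta - Q0 @ x
        step = sla.cho_solve((L, True), g)
        decrement = float(g @ step)
        scale = 1.0
        for _ in range(30):
            x_new = x + scale * step
            eta_new = M @ x_new
            ll_new, grad_new, w_new = design.lik_terms(eta_new, phi)
            f_new = ll_new - 0.5 * x_new @ Q0 @ x_new if np.isfinite(ll_new) else -np.inf
            if np.isfinite(f_new) and f_new >= f - 1e-12:
                break
            scale *= 0.5
        else:
            raise APCFitError("Newton line search failed", {"iteration": it, "f": f})
        x, eta, f, grad_eta, w = x_new, eta_new, f_new, grad_new, w_new
        if decrement * scale < 1e-9 * (1.0 + abs(f)):
            break
    else:
        raise APCFitError("Newton iterations did not converge", {"f": f})
    # refresh the factor at the accepted point
    H = Q0 + (M * w[:, None]).T @ M
    try:
        L = np.linalg.cholesky(H)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(H + 1e-8 * np.eye(design.p))
    return x, L, f, it + 1


def _theta_logprior(theta: np.ndarray, spec: APCModelSpec) -> float:
    """Hyper prior in theta = log(tau) coordinates (PC prior + Jacobian)."""
    lam = pc_prior_rate(spec.pc_u, spec.pc_alpha)
    sigma = np.exp(-0.5 * theta[:3])
    lp = float(np.sum(np.log(lam) - lam * sigma + np.log(sigma / 2.0)))
    if spec.overdispersion == "on":
        # weak lognormal prior on the NB dispersion phi = exp(theta[3])
        lp += -0.5 * ((theta[3] - np.log(100.0)) / 2.0) ** 2
    return lp


def _log_marginal(theta, design, x_warm):
    """Laplace approximation to the log marginal posterior of theta."""
    spec = design.spec
    if np.max(np.abs(theta[:3])) > _THETA_BOUND:
        return -1e12, x_warm, None, None
    taus = np.exp(theta[:3])
    phi = float(np.exp(theta[3])) if spec.overdispersion == "on" else None
    Q0 = design.prior_precision(taus)
    try:
        x_star, L, f, _ = _newton_mode(design, Q0, phi, x_warm)
    except APCFitError:
        return -1e12, x_warm, None, None
    lm = (
        f
        + 0.5 * float(design.ranks @ theta[:3])
        + _theta_logprior(theta, spec)
        - float(np.sum(np.log(np.diag(L))))
    )
    return lm, x_star, L, f


@dataclasses.dataclass
class APCFit:
    """Joint posterior samples and diagnostics of a fitted APC model.

    All arrays are indexed by sample first: ``eta`` is (S, A, T); the
    effect arrays carry the full-length constrained vectors per sample.
    ``sigma_*`` and ``phi`` are the hyperparameter values attached to each
    sample's hyper draw.
    """

    spec: APCModelSpec
    grid: LexisGrid
    eta: np.ndarray
    mu: np.ndarray
    age: np.ndarray
    period: np.ndarray
    cohort: np.ndarray
    delta: np.ndarray
    sigma_age: np.ndarray
    sigma_period: np.ndarray
    sigma_cohort: np.ndarray
    phi: np.ndarray | None
    theta_mode: np.ndarray
    theta_cov: np.ndarray
    log_marginal_mode: float
    diagnostics: dict

    @property
    def sample_count(self) -> int:
        return self.eta.shape[0]

    def eta_mean(self) -> np.ndarray:
        return self.eta.mean(axis=0)

    def eta_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        q = (1.0 - level) / 2.0
        lo = np.quantile(self.eta, q, axis=0)
        hi = np.quantile(self.eta, 1.0 - q, axis=0)
        return lo, hi

    def rate_samples(self) -> np.ndarray:
        """Posterior samples of age-specific rates per person-year, (S, A, T)."""
        return np.exp(self.eta)

    def loglik_matrix(self) -> np.ndarray:
        """Per-sample, per-cell full log-likelihood (S, A*T), factorials included."""
        y = self.grid.counts.ravel()
        n = self.grid.person_years.ravel()
        eta = self.eta.reshape(self.sample_count, -1)
        m = n[None, :] * np.exp(eta)
        if self.spec.overdispersion == "on":
            phi = self.phi[:, None]
            return (
                gammaln(y + phi)
                - gammaln(phi)
                - gammaln(y + 1.0)
                + phi * np.log(phi / (phi + m))
                + y * np.log(m / (phi + m))
            )
        return y[None, :] * np.log(m) - m - gammaln(y + 1.0)[None, :]


def fit_apc(grid: LexisGrid, spec: APCModelSpec) -> APCFit:
    """Fit the Bayesian APC model and return joint posterior samples.

    Raises :class:`APCFitError` (with diagnostics) when the hyperparameter
    optimization or the inner Newton solver fails to converge.
    """
    if grid.T < 4:
        raise ValueError("need at least 4 periods to fit an APC model")
    design = _Design(grid, spec)
    d_theta = 4 if spec.overdispersion == "on" else 3
    theta0 = np.full(d_theta, np.log(100.0))  # sigma = 0.1 start
    if spec.overdispersion == "on":
        theta0[3] = np.log(100.0)

    warm = {"x": np.zeros(design.p)}

    def neg_lm(theta):
        lm, x_star, _, _ = _log_marginal(np.asarray(theta, dtype=float), design, warm["x"])
        if np.isfinite(lm) and lm > -1e11:
            warm["x"] = x_star
        return -lm

    res = minimize(
        neg_lm,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 5e-4, "maxfev": 400},
    )
    theta_star = np.asarray(res.x, dtype=float)
    lm_star, x_star, L_star, _ = _log_marginal(theta_star, design, warm["x"])
    if not np.isfinite(lm_star) or lm_star <= -1e11:
        raise APCFitError(
            "hyperparameter optimization did not converge",
            {"theta": theta_star.tolist(), "nelder_mead": res.message},
        )

    # numeric Hessian of -log marginal at the mode (central differences)
    h = 0.2
    H = np.zeros((d_theta, d_theta))
    cache: dict[tuple, float] = {}

    def lm_at(t):
        key = tuple(np.round(t, 12))
        if key not in cache:
            cache[key] = _log_marginal(np.asarray(t), design, x_star)[0]
        return cache[key]

    f0 = lm_star
    for i in range(d_theta):
        ei = np.zeros(d_theta)
        ei[i] = h
        H[i, i] = -(lm_at(theta_star + ei) - 2 * f0 + lm_at(theta_star - ei)) / h**2
        for j in range(i + 1, d_theta):
            ej = np.zeros(d_theta)
            ej[j] = h
            H[i, j] = H[j, i] = -(
                lm_at(theta_star + ei + ej)
                - lm_at(theta_star + ei - ej)
                - lm_at(theta_star - ei + ej)
                + lm_at(theta_star - ei - ej)
            ) / (4 * h**2)
    evals, evecs = np.linalg.eigh((H + H.T) / 2.0)
    evals = np.clip(evals, 0.16, None)  # cap hyper sampling sd at 2.5 per direction
    theta_cov = (evecs / evals) @ evecs.T

    rng = np.random.default_rng(spec.seed)
    S = spec.sample_count
    n_theta = min(spec.theta_points, S)
    Lcov = np.linalg.cholesky(theta_cov)
    thetas = theta_star[None, :] + rng.standard_normal((n_theta, d_theta)) @ Lcov.T
    modes, chols = [], []
    for t in thetas:
        lm_t, x_t, L_t, _ = _log_marginal(t, design, x_star)
        if L_t is None:  # degenerate hyper draw; fall back to the mode point
            x_t, L_t = x_star, L_star
            t[:] = theta_star
        modes.append(x_t)
        chols.append(L_t)

    idx = np.arange(S) % n_theta
    X = np.empty((S, design.p))
    Z = rng.standard_normal((S, design.p))
    for j in range(n_theta):
        sel = idx == j
        if not sel.any():
            continue
        # x = mode + L^{-T} z gives x ~ N(mode, H^{-1}) with H = L L'
        X[sel] = modes[j] + sla.solve_triangular(chols[j], Z[sel].T, lower=True, trans="T").T

    eta_lin = X @ design.M.T + design.fixed_offset[None, :]
    A, T = grid.A, grid.T
    C = grid.n_cohorts
    age_s = X[:, design.sl_age] @ design.Ba.T
    per_s = X[:, design.sl_per] @ design.Bt.T
    coh_s = X[:, design.sl_coh] @ design.Bc.T
    K = len(spec.covariates)
    delta = np.zeros((S, K))
    free_iter = iter(range(design.sl_del.start, design.sl_del.stop))
    for k, cov in enumerate(spec.covariates):
        if cov.coefficient is None:
            delta[:, k] = X[:, next(free_iter)]
        else:
            delta[:, k] = cov.coefficient
    sig = np.exp(-0.5 * thetas[idx, :3])
    phi = np.exp(thetas[idx, 3]) if spec.overdispersion == "on" else None

    return APCFit(
        spec=spec,
        grid=grid,
        eta=eta_lin.reshape(S, A, T),
        mu=X[:, 0],
        age=age_s,
        period=per_s,
        cohort=coh_s,
        delta=delta,
        sigma_age=sig[:, 0],
        sigma_period=sig[:, 1],
        sigma_cohort=sig[:, 2],
        phi=phi,
        theta_mode=theta_star,
        theta_cov=theta_cov,
        log_marginal_mode=lm_star,
        diagnostics={
            "optimizer_evals": res.nfev,
            "optimizer_message": str(res.message),
            "n_theta_points": n_theta,
            "latent_dim": design.p,
            "n_cohorts": C,
        },
    )
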