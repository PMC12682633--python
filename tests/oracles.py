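"""Independent oracle implementations used only by the test suite.

Everything here is coded separately from the package internals: the log
posterior is a term-by-term summation over explicit loops, the MCMC sampler
is a plain adaptive random-walk Metropolis over its own reduced
parameterization, and the scoring/regression oracles are direct formula
transcriptions.  None of it reuses the package's design-matrix or Laplace
machinery.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_log_posterior(
    mu, age, period, cohort, sigmas, grid, spec, delta=(),
) -> float:
    """Term-by-term log posterior (same additive-constant convention as the
    package: Poisson term without factorials, RW prior up to a constant,
    exact PC densities, normal terms -x^2/(2 sd^2) - ln sd)."""
    A, T = grid.A, grid.T
    M = grid.age_width
    y = grid.counts
    n = grid.person_years
    xs = []
    for cov in spec.covariates:
        lookup = dict(zip(cov.years, cov.values))
        x = np.array([lookup[int(v)] for v in grid.years])
        xs.append(x - x.mean())
    total = 0.0
    for a in range(A):
        for t in range(T):
            c = M * (A - 1 - a) + t
            eta = mu + age[a] + period[t] + cohort[c]
            for k, cov in enumerate(spec.covariates):
                coef = cov.coefficient if cov.coefficient is not None else delta[k]
                eta += coef * xs[k][t]
            mean = n[a, t] * math.exp(eta)
            total += y[a, t] * math.log(mean) - mean
    orders = (spec.rw_order_age, spec.rw_order_period, spec.rw_order_cohort)
    for u, order, sigma in zip((age, period, cohort), orders, sigmas):
        tau = 1.0 / sigma**2
        penalty = 0.0
        d = np.array(u, dtype=float)
        for _ in range(order):
            d = d[1:] - d[:-1]
        for v in d:
            penalty += v * v
        total += -(tau / 2.0) * penalty + ((len(u) - order) / 2.0) * math.log(tau)
        lam = -math.log(spec.pc_alpha) / spec.pc_u
        total += math.log(lam) - lam * sigma
    total += -0.5 * (mu / spec.mu_prior_sd) ** 2 - math.log(spec.mu_prior_sd)
    for k, cov in enumerate(spec.covariates):
        if cov.coefficient is None:
            total += -0.5 * (delta[k] / spec.delta_prior_sd) ** 2 - math.log(
                spec.delta_prior_sd
            )
    return total


def _subspace_basis(m: int, extra_linear: bool) -> np.ndarray:
    """Orthonormal basis of {sum u = 0} (and zero linear trend if asked),
    built by Gram-Schmidt against the constraint vectors -- deliberately a
    different construction from the package's null-space call."""
    cons = [np.ones(m)]
    if extra_linear:
        cons.append(np.arange(m, dtype=float) - (m - 1) / 2.0)
    basis = []
    for j in range(m):
        v = np.zeros(m)
        v[j] = 1.0
        for c in cons:
            v = v - (v @ c) / (c @ c) * c
        for b in basis:
            v = v - (v @ b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.column_stack(basis)


def mcmc_posterior(
    grid,
    spec,
    n_iter: int = 120_000,
    n_adapt: int = 40_000,
    seed: int = 0,
    thin: int = 10,
):
    """Long-run adaptive random-walk Metropolis over (latent, log-precisions).

    Samples the same posterior ``fit_apc`` targets (sum-to-zero constraints,
    cohort detrended, PC priors on the random-walk scales) and returns a
    dict with the posterior mean of eta and the retained eta draws.

    Uses the non-centered parameterization (effect = sigma * whitened field)
    so the sampler does not face the scale/field funnel: for a reduced block
    of dimension p and penalty rank r, u = exp(-theta/2) * F w has
    log-density -(1/2) ||D F w||^2 + ((r - p)/2) theta in (w, theta).
    """
    A, T, C = grid.A, grid.T, grid.n_cohorts
    M = grid.age_width
    Fa = _subspace_basis(A, extra_linear=False)
    Ft = _subspace_basis(T, extra_linear=False)
    Fc = _subspace_basis(C, extra_linear=True)
    K = sum(1 for c in spec.covariates if c.coefficient is None)
    dim = 1 + Fa.shape[1] + Ft.shape[1] + Fc.shape[1] + K + 3
    sl = {}
    pos = 1
    for name, width in (
        ("age", Fa.shape[1]),
        ("period", Ft.shape[1]),
        ("cohort", Fc.shape[1]),
        ("delta", K),
    ):
        sl[name] = slice(pos, pos + width)
        pos += width
    sl["theta"] = slice(pos, pos + 3)

    cidx = np.zeros((A, T), dtype=int)
    for a in range(A):
        for t in range(T):
            cidx[a, t] = M * (A - 1 - a) + t
    y = grid.counts
    n = grid.person_years
    xs = []
    free_idx = []
    for k, cov in enumerate(spec.covariates):
        lookup = dict(zip(cov.years, cov.values))
        x = np.array([lookup[int(v)] for v in grid.years])
        xs.append(x - x.mean())
        if cov.coefficient is None:
            free_idx.append(k)
    orders = (spec.rw_order_age, spec.rw_order_period, spec.rw_order_cohort)
    lam = -math.log(spec.pc_alpha) / spec.pc_u

    def effects(z):
        theta = z[sl["theta"]]
        sig = np.exp(-theta / 2.0)
        age = sig[0] * (Fa @ z[sl["age"]])
        period = sig[1] * (Ft @ z[sl["period"]])
        cohort = sig[2] * (Fc @ z[sl["cohort"]])
        return age, period, cohort, theta

    def build_eta(z):
        mu = z[0]
        age, period, cohort, _ = effects(z)
        eta = mu + age[:, None] + period[None, :] + cohort[cidx]
        kk = 0
        for k, cov in enumerate(spec.covariates):
            if cov.coefficient is None:
                coef = z[sl["delta"]][kk]
                kk += 1
            else:
                coef = cov.coefficient
            eta = eta + coef * xs[k][None, :]
        return eta

    dims_red = {"age": Fa.shape[1], "period": Ft.shape[1], "cohort": Fc.shape[1]}
    ranks = {
        "age": A - spec.rw_order_age,
        "period": T - spec.rw_order_period,
        "cohort": C - spec.rw_order_cohort,
    }

    def logpost(z):
        theta = z[sl["theta"]]
        if np.max(np.abs(theta)) > 40:
            return -np.inf
        eta = build_eta(z)
        with np.errstate(over="ignore", invalid="ignore"):
            ll = float(np.sum(y * eta - n * np.exp(eta)))
        if not np.isfinite(ll):
            return -np.inf
        lp = ll
        whitened = {
            "age": Fa @ z[sl["age"]],
            "period": Ft @ z[sl["period"]],
            "cohort": Fc @ z[sl["cohort"]],
        }
        for name, order, th in zip(("age", "period", "cohort"), orders, theta):
            w = whitened[name]
            lp += -0.5 * float(np.sum(np.diff(w, order) ** 2))
            lp += ((ranks[name] - dims_red[name]) / 2.0) * th
            sigma = math.exp(-th / 2.0)
            lp += math.log(lam) - lam * sigma + math.log(sigma / 2.0)
        lp += -0.5 * (z[0] / spec.mu_prior_sd) ** 2
        for v in z[sl["delta"]]:
            lp += -0.5 * (v / spec.delta_prior_sd) ** 2
        return lp

    from scipy.optimize import minimize as _minimize

    rng = np.random.default_rng(seed)
    z0 = np.zeros(dim)
    z0[sl["theta"]] = np.log(100.0)
    opt = _minimize(lambda v: -logpost(v), z0, method="BFGS",
                    options={"maxiter": 2000, "gtol": 1e-6})
    z = opt.x.copy()
    # exact central-difference Hessian at the mode for the proposal shape
    h = 1e-4
    Hm = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            ei = np.zeros(dim); ei[i] = h
            ej = np.zeros(dim); ej[j] = h
            val = -(
                logpost(z + ei + ej) - logpost(z + ei - ej)
                - logpost(z - ei + ej) + logpost(z - ei - ej)
            ) / (4 * h * h)
            Hm[i, j] = Hm[j, i] = val
    evals, evecs = np.linalg.eigh((Hm + Hm.T) / 2.0)
    evals = np.clip(evals, 1e-4, None)
    prop_cov = (evecs / evals) @ evecs.T
    chol = np.linalg.cholesky(prop_cov)
    lp = logpost(z)
    scale = 2.38 / math.sqrt(dim)
    mean_acc = 0.0
    recent_acc = 0.0
    eta_sum = np.zeros((A, T))
    eta_draws = []
    kept = 0
    for it in range(n_iter + n_adapt):
        prop = z + scale * (chol @ rng.standard_normal(dim))
        lp_prop = logpost(prop)
        if math.log(rng.random()) < lp_prop - lp:
            z, lp = prop, lp_prop
            mean_acc += 1.0
            recent_acc += 1.0
        if it < n_adapt:
            if it % 500 == 499:
                scale *= math.exp((recent_acc / 500.0 - 0.234) * 1.0)
                recent_acc = 0.0
        elif (it - n_adapt) % thin == 0:
            eta = build_eta(z)
            eta_sum += eta
            eta_draws.append(eta.copy())
            kept += 1
    return {
        "eta_mean": eta_sum / kept,
        "eta_draws": np.array(eta_draws),
        "acceptance": mean_acc / (n_iter + n_adapt),
    }


def ols_log_slope(years, values):
    """Normal-equations slope and its standard error for ln(values) ~ years."""
    x = np.asarray(years, dtype=float)
    z = np.log(np.asarray(values, dtype=float))
    xbar, zbar = x.mean(), z.mean()
    sxx = np.sum((x - xbar) ** 2)
    beta = np.sum((x - xbar) * (z - zbar)) / sxx
    alpha = zbar - beta * xbar
    resid = z - alpha - beta * x
    dof = x.size - 2
    se = math.sqrt(np.sum(resid**2) / dof / sxx)
    return beta, se


def crps_brute(samples, y):
    """Double-loop transcription of the ensemble CRPS estimator."""
    x = np.asarray(samples, dtype=float)
    S = x.size
    t1 = sum(abs(v - y) for v in x) / S
    t2 = sum(abs(a - b) for a in x for b in x) / (2.0 * S * S)
    return t1 - t2


def poisson_logpmf(y, mean):
    return y * math.log(mean) - mean - math.lgamma(y + 1.0)
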