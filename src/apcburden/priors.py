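"""Random-walk smoothness priors and the penalized-complexity (PC) prior.

Age, period and cohort effects are modelled as intrinsic Gaussian random
walks of order 1 or 2.  The RW(k) log-density of a vector ``u`` with
precision ``tau`` is, up to an additive constant,

    -(tau/2) * || D_k u ||^2  +  ((len(u) - k) / 2) * ln(tau)

where ``D_k`` is the k-th forward-difference matrix.  The null space of the
penalty contains constants (k=1) and constants plus linear trends (k=2);
those directions are what the APC identifiability constraints remove.

The PC prior shrinks each random walk toward its base model by placing an
exponential distribution on the walk's standard deviation sigma, with rate
lambda = -ln(alpha) / U so that P(sigma > U) = alpha.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "difference_matrix",
    "rw_structure",
    "rw_log_prior",
    "pc_prior_rate",
    "pc_prior_logdensity",
]


def difference_matrix(m: int, order: int) -> np.ndarray:
    """Dense ``(m-order) x m`` forward-difference matrix of the given order."""
    if order < 1:
        raise ValueError("difference order must be >= 1")
    if m <= order:
        raise ValueError(f"need at least order+1={order + 1} points, got {m}")
    D = np.eye(m)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def rw_structure(m: int, order: int) -> np.ndarray:
    """Structure matrix ``K = D'D`` of an order-``order`` random walk on m points.

    ``K`` is rank ``m - order``; its null space is spanned by polynomials of
    degree < order in the index.
    """
    D = difference_matrix(m, order)
    return D.T @ D


def rw_log_prior(u: np.ndarray, order: int, tau: float) -> float:
    """Improper RW(order) log-density of ``u`` at precision ``tau``, up to a constant.

    Returns ``-(tau/2) * sum((D u)^2) + ((len(u)-order)/2) * ln(tau)``.
    """
    if tau <= 0:
        raise ValueError(f"random-walk precision must be positive, got {tau}")
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size < order + 1:
        raise ValueError("effect vector must be 1-d with length >= order+1")
    diffs = np.diff(u, n=order)
    rank = u.size - order
    return float(-(tau / 2.0) * np.sum(diffs**2) + (rank / 2.0) * np.log(tau))


def _check_pc_params(U: float, alpha: float) -> None:
    if not (U > 0):
        raise ValueError(f"PC prior scale U must be positive, got {U}")
    if not (0 < alpha < 1):
        raise ValueError(f"PC prior tail probability must be in (0,1), got {alpha}")


def pc_prior_rate(U: float, alpha: float) -> float:
    """Exponential rate lambda = -ln(alpha)/U, so that P(sigma > U) = alpha."""
    _check_pc_params(U, alpha)
    return -np.log(alpha) / U


def pc_prior_logdensity(sigma: float, U: float, alpha: float) -> float:
    """Log-density of the PC prior for a standard deviation ``sigma``.

    The prior is Exponential(lambda) on sigma with lambda = -ln(alpha)/U:
    ``ln lambda - lambda * sigma`` for sigma >= 0.
    """
    _check_pc_params(U, alpha)
    if sigma < 0:
        raise ValueError(f"standard deviation must be nonnegative, got {sigma}")
    lam = pc_prior_rate(U, alpha)
    return float(np.log(lam) - lam * sigma)
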