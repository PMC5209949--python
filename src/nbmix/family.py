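"""Negative binomial likelihood machinery on the log-link scale.

The count model is

    P(y) = Gamma(y + theta) / (Gamma(theta) y!)
           * (theta / (mu + theta))**theta * (mu / (mu + theta))**y

with mean ``mu`` and shape ``theta``; the variance is ``mu + mu**2/theta``,
so ``theta`` controls over-dispersion and ``theta -> inf`` recovers the
Poisson model.  Everything needed by the iterative weighted least squares
(IWLS) fit lives here: the log-pmf, its first and second derivatives with
respect to the linear predictor ``eta = log(mu)``, the pseudo-data
construction, and the Newton-Raphson profile update of ``theta``.

Derivatives in ``eta`` (with ``mu = exp(eta)``):

    L'(y|eta, theta)  =  theta * (y - mu) / (mu + theta)
    L''(y|eta, theta) = -theta * mu * (y + theta) / (mu + theta)**2

``L'' < 0`` for every ``mu > 0``, ``theta > 0``, so the pseudo-weights
``w = -L''`` are strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .exceptions import DomainError

logger = logging.getLogger(__name__)

#: floor applied to pseudo-weights; avoids singular weighted LMMs on
#: fits driven to extreme linear predictors
WEIGHT_FLOOR = 1e-10

__all__ = [
    "NBParams",
    "PseudoData",
    "nb_log_pmf",
    "nb_moments",
    "nb_eta_derivatives",
    "compute_pseudo_data",
    "update_theta",
    "WEIGHT_FLOOR",
]


@dataclass(frozen=True)
class NBParams:
    """Mean and shape of a negative binomial distribution.

    ``mu`` may be a scalar or a per-sample vector; ``theta`` is a scalar
    shared across samples.
    """

    mu: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        if mu.size == 0 or np.any(~np.isfinite(mu)) or np.any(mu <= 0):
            raise DomainError("mu must be positive and finite")
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise DomainError("theta must be positive and finite")
        object.__setattr__(self, "mu", mu)


@dataclass(frozen=True)
class PseudoData:
    """Working response ``t`` and weights ``w`` of the surrogate LMM."""

    t: np.ndarray
    w: np.ndarray


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise DomainError("empty count vector")
    if not np.issubdtype(y.dtype, np.number):
        raise DomainError("counts must be numeric")
    yf = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(yf)) or np.any(yf < 0) or np.any(yf != np.round(yf)):
        raise DomainError("counts must be non-negative integers")
    return yf


def nb_log_pmf(y, params: NBParams) -> np.ndarray:
    """Elementwise log negative binomial pmf, via log-gamma functions."""
    yf = _check_counts(y)
    theta = float(params.theta)
    mu = np.asarray(params.mu, dtype=float)
    lse = np.log(mu + theta)
    return (
        special.gammaln(yf + theta)
        - special.gammaln(theta)
        - special.gammaln(yf + 1.0)
        + theta * (np.log(theta) - lse)
        + special.xlogy(yf, mu)
        - yf * lse
    )


def nb_moments(params: NBParams):
    """Mean and variance implied by (mu, theta): mu and mu + mu**2/theta."""
    mu = np.asarray(params.mu, dtype=float)
    return mu, mu + mu**2 / params.theta


def nb_eta_derivatives(y, eta, theta: float):
    """First and second derivatives of the NB log-likelihood in eta.

    Computed in overflow-safe form via ``log(mu + theta) =
    logaddexp(eta, log theta)`` so that arbitrarily large or small ``eta``
    never produce NaN.  Returns ``(L1, L2)`` with ``L2 < 0`` elementwise.
    """
    yf = _check_counts(y)
    eta = np.asarray(eta, dtype=float)
    if np.any(~np.isfinite(eta)):
        raise DomainError("eta must be finite")
    if not np.isfinite(theta) or theta <= 0:
        raise DomainError("theta must be positive")
    lse = np.logaddexp(eta, np.log(theta))  # log(mu + theta)
    frac = np.exp(eta - lse)                # mu / (mu + theta), in (0, 1)
    inv = np.exp(-lse)                      # 1 / (mu + theta)
    L1 = theta * (yf * inv - frac)
    L2 = -theta * (yf + theta) * frac * inv
    return L1, L2


def compute_pseudo_data(y, eta_hat, theta_hat: float,
                        weight_floor: float = WEIGHT_FLOOR,
                        scoring: str = "observed") -> PseudoData:
    """Pseudo-response ``t = eta - L1/L2`` and pseudo-weights ``w = -L2``.

    ``scoring="observed"`` uses the observed second derivative,
    ``w = -L''(y|eta, theta)``.  ``scoring="fisher"`` replaces it by its
    expectation over y (Fisher scoring, the classical IWLS working data):

        w = mu * theta / (mu + theta),     t = eta + (y - mu) / mu

    for which ``Var(t | eta) = 1/w`` holds exactly under the model, so
    the surrogate residual variance stays near 1 and Wald standard
    errors are calibrated.  Weights that underflow below
    ``weight_floor`` are clamped (with a warning) so the downstream
    weighted LMM stays non-singular.
    """
    L1, L2 = nb_eta_derivatives(y, eta_hat, theta_hat)
    if scoring == "observed":
        w = -L2
    elif scoring == "fisher":
        # E[-L''] = mu*theta/(mu+theta), stable form as for L2
        eta = np.asarray(eta_hat, dtype=float)
        lse = np.logaddexp(eta, np.log(theta_hat))
        w = theta_hat * np.exp(eta - lse)
    else:
        raise DomainError(f"unknown scoring {scoring!r}")
    n_clamped = int(np.sum(w < weight_floor))
    if n_clamped:
        logger.warning("clamped %d pseudo-weights below %.1e", n_clamped, weight_floor)
        w = np.maximum(w, weight_floor)
    t = np.asarray(eta_hat, dtype=float) + L1 / w
    return PseudoData(t=t, w=w)


def _profile_loglik(y, mu, theta: float) -> float:
    return float(np.sum(nb_log_pmf(y, NBParams(mu=mu, theta=theta))))


def _score_hess_theta(y, mu, theta: float):
    """Gradient and Hessian of the profile log-likelihood in theta."""
    mt = mu + theta
    g = np.sum(
        special.digamma(y + theta) - special.digamma(theta)
        + np.log(theta) + 1.0 - np.log(mt) - (y + theta) / mt
    )
    h = np.sum(
        special.polygamma(1, y + theta) - special.polygamma(1, theta)
        + 1.0 / theta - 1.0 / mt - (mu - y) / mt**2
    )
    return float(g), float(h)


def update_theta(y, mu_hat, theta_init: float = 1.0,
                 bounds: tuple[float, float] = (1e-2, 1e4)) -> float:
    """Update the shape parameter by maximizing the NB likelihood at fixed mu.

    Newton-Raphson on ``log(theta)`` with backtracking; falls back to a
    bounded 1-D search when Newton fails to improve the likelihood.  The
    result is clamped to ``bounds`` (with a warning when the optimum lies
    outside) and never has lower likelihood than ``theta_init``.
    """
    yf = _check_counts(y)
    mu = np.asarray(mu_hat, dtype=float)
    if np.any(mu <= 0) or np.any(~np.isfinite(mu)):
        raise DomainError("mu_hat must be positive and finite")
    lo, hi = bounds
    if not (0 < lo < hi):
        raise DomainError("theta bounds must be positive and ordered")
    zlo, zhi = np.log(lo), np.log(hi)
    z = float(np.clip(np.log(theta_init), zlo, zhi))
    ll0 = _profile_loglik(yf, mu, np.exp(z))

    ll = ll0
    ok = False
    for _ in range(50):
        theta = np.exp(z)
        g, h = _score_hess_theta(yf, mu, theta)
        gz = theta * g
        hz = theta**2 * h + theta * g
        if abs(gz) < 1e-9 * max(1.0, yf.size):
            ok = True
            break
        step = -gz / hz if hz < 0 else np.sign(gz)
        step = float(np.clip(step, -2.0, 2.0))
        # backtrack to guarantee ascent
        accepted = False
        for _ in range(12):
            z_new = float(np.clip(z + step, zlo, zhi))
            ll_new = _profile_loglik(yf, mu, np.exp(z_new))
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if abs(z_new - z) < 1e-12:
            z, ll = z_new, ll_new
            ok = True
            break
        z, ll = z_new, ll_new
    at_bound = z <= zlo + 1e-9 or z >= zhi - 1e-9
    if not ok and not at_bound:
        res = optimize.minimize_scalar(
            lambda zz: -_profile_loglik(yf, mu, np.exp(zz)),
            bounds=(zlo, zhi), method="bounded",
            options={"xatol": 1e-10},
        )
        if np.isfinite(res.fun) and -res.fun >= ll:
            z, ll = float(res.x), float(-res.fun)
    if z <= zlo + 1e-9 or z >= zhi - 1e-9:
        logger.warning("theta update clamped at bound %.3g", np.exp(z))
    if ll < ll0:
        return float(np.exp(np.clip(np.log(theta_init), zlo, zhi)))
    return float(np.exp(z))
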