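"""Weighted linear mixed model with a single random intercept.

Fits

    t_i = offset_i + X_i beta + b_{g(i)} + w_i^{-1/2} e_i,
    b ~ N_K(0, tau^2 I),   e ~ N_n(0, sigma^2 I)

by restricted maximum likelihood (REML), profiling everything out except
the single variance ratio ``lambda = tau^2 / sigma^2``.  With group
indicators Z, the marginal covariance is ``sigma^2 V0(lambda)`` where
``V0 = diag(1/w) + lambda Z Z'``; the Woodbury identity gives, per group k
with weight sum ``s_k``,

    V0^{-1} v = w v - c_k w (sum of w v over group k),  c_k = lambda/(1 + lambda s_k)
    log|V0|   = sum_k log(1 + lambda s_k) - sum_i log w_i

so each evaluation of the profiled REML criterion costs O(n p).  The
outer problem is a 1-D bounded search over log(lambda).

This engine is the inner solver of the IWLS algorithm; it is also used
directly (with unit weights) by the transformed-response linear mixed
model comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import DomainError, RankDeficientError

__all__ = ["LMMSolution", "fit_weighted_lmm", "weighted_ls"]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class LMMSolution:
    """REML solution of the weighted random-intercept model."""

    beta: np.ndarray
    beta_cov: np.ndarray
    b: np.ndarray
    tau2: float
    sigma2: float
    loglik: float
    lam: float
    boundary: bool
    fitted: np.ndarray = field(repr=False, default=None)


def _validate(t, X, w, offset):
    t = np.asarray(t, dtype=float)
    X = np.asarray(X, dtype=float)
    n = t.shape[0]
    if X.ndim != 2 or X.shape[0] != n:
        raise DomainError("X must be n x p")
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    for name, arr in (("t", t), ("X", X), ("weights", w), ("offset", offset)):
        if np.any(~np.isfinite(arr)):
            raise DomainError(f"non-finite values in {name}")
    if w.shape[0] != n or offset.shape[0] != n:
        raise DomainError("weights/offset length mismatch")
    if np.any(w <= 0):
        raise DomainError("weights must be strictly positive")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError("fixed-effect design is rank deficient")
    return t, X, w, offset


def weighted_ls(t, X, w=None, offset=None):
    """Weighted least squares (no random effect); returns an LMMSolution
    with tau2 = 0 and b empty.  Used when the variance component is pinned
    to zero and for the one-group degenerate reduction."""
    t, X, w, offset = _validate(t, X, w, offset)
    n, p = X.shape
    r = t - offset
    WX = w[:, None] * X
    A = X.T @ WX
    beta = np.linalg.solve(A, WX.T @ r)
    res = r - X @ beta
    q = max(float(np.sum(w * res**2)), 1e-30)
    dof = max(n - p, 1)
    sigma2 = q / dof
    cov = sigma2 * np.linalg.inv(A)
    ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + dof
                 - float(np.sum(np.log(w)))
                 + float(np.linalg.slogdet(A)[1]))
    return LMMSolution(beta=beta, beta_cov=cov, b=np.zeros(0), tau2=0.0,
                       sigma2=sigma2, loglik=ll, lam=0.0, boundary=True,
                       fitted=offset + X @ beta)


def fit_weighted_lmm(t, X, groups, weights=None, offset=None,
                     n_groups: int | None = None,
                     log_lambda_bounds: tuple[float, float] = _LOG_LAMBDA_BOUNDS,
                     xatol: float = 1e-9) -> LMMSolution:
    """REML fit of the weighted random-intercept LMM.

    Parameters
    ----------
    t : (n,) pseudo-response (or transformed response).
    X : (n, p) fixed-effect design, full column rank.
    groups : (n,) integer group codes in 0..K-1.
    weights : (n,) strictly positive observation weights (default 1).
    offset : (n,) known term added to the mean (default 0).
    n_groups : number of groups K (default ``max(groups) + 1``).

    A boundary solution (tau2 ~ 0 or at the upper lambda bound) is
    flagged via ``LMMSolution.boundary``.
    """
    t, X, w, offset = _validate(t, X, weights, offset)
    groups = np.asarray(groups)
    if groups.shape[0] != t.shape[0]:
        raise DomainError("groups length mismatch")
    groups = groups.astype(np.intp)
    K = int(n_groups) if n_groups is not None else int(groups.max()) + 1
    n, p = X.shape

    r = t - offset
    wr = w * r
    WX = w[:, None] * X
    XtWX = X.T @ WX
    XtWr = X.T @ wr
    rtWr = float(wr @ r)
    s = np.bincount(groups, weights=w, minlength=K)           # per-group weight sums
    Sr = np.bincount(groups, weights=wr, minlength=K)
    SX = np.column_stack([np.bincount(groups, weights=WX[:, j], minlength=K)
                          for j in range(p)])
    sum_log_w = float(np.sum(np.log(w)))
    dof = n - p
    if dof <= 0:
        raise DomainError("need more observations than fixed effects")

    def crit_parts(lam: float):
        c = lam / (1.0 + lam * s)
        A = XtWX - (SX.T * c) @ SX
        u = XtWr - SX.T @ (c * Sr)
        try:
            beta = np.linalg.solve(A, u)
        except np.linalg.LinAlgError:
            return None
        q = rtWr - float(np.sum(c * Sr**2)) - float(u @ beta)
        if not np.isfinite(q):
            return None
        # exactly collinear response: keep a floor so degenerate features
        # still return beta (with ~zero residual variance) instead of raising
        q = max(q, 1e-30)
        sldA = np.linalg.slogdet(A)[1]
        sldV0 = float(np.sum(np.log1p(lam * s))) - sum_log_w
        crit = dof * np.log(q) + sldV0 + sldA
        return crit, beta, A, q, sldV0, sldA

    def crit(zeta: float) -> float:
        parts = crit_parts(np.exp(zeta))
        return np.inf if parts is None else parts[0]

    zlo, zhi = log_lambda_bounds
    res = optimize.minimize_scalar(crit, bounds=(zlo, zhi), method="bounded",
                                   options={"xatol": xatol})
    zeta = float(res.x)
    # the bounded minimizer can stall near an edge; keep the better endpoint
    for z_edge in (zlo, zhi):
        if crit(z_edge) < crit(zeta):
            zeta = z_edge
    lam = float(np.exp(zeta))
    parts = crit_parts(lam)
    if parts is None:
        raise DomainError("REML profile criterion is degenerate")
    _, beta, A, q, sldV0, sldA = parts
    sigma2 = q / dof
    tau2 = lam * sigma2
    cov = sigma2 * np.linalg.inv(A)
    # BLUPs: b_k = lambda * (sum_k w res) / (1 + lambda s_k)
    res_fix = r - X @ beta
    Swres = np.bincount(groups, weights=w * res_fix, minlength=K)
    b = lam * Swres / (1.0 + lam * s)
    boundary = zeta <= zlo + 1e-2 or zeta >= zhi - 1e-2
    ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + dof + sldV0 + sldA)
    fitted = offset + X @ beta + b[groups]
    return LMMSolution(beta=beta, beta_cov=cov, b=b, tau2=tau2, sigma2=sigma2,
                       loglik=ll, lam=lam, boundary=boundary, fitted=fitted)
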