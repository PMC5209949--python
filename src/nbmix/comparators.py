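"""Baseline per-feature association tests used in the benchmark study.

Four comparators to the NB mixed model, each testing the host-factor
coefficient beta:

* ``NB``          — fixed-effects NB regression with a log(T) offset,
                    theta estimated jointly (ignores the grouping).
* ``LMM_log``     — random-intercept LMM on log((y+1)/T).
* ``LMM_arcsine`` — random-intercept LMM on arcsin(sqrt(y/T)).
* ``LM``          — plain linear model on arcsin(sqrt(y/T)) (ignores the
                    grouping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError
from .lmm import fit_weighted_lmm, weighted_ls
from .model import FitControl, NegativeBinomialMixedModel

__all__ = [
    "ComparatorResult",
    "transform_log",
    "transform_arcsine",
    "fit_nb_glm",
    "fit_lmm_transformed",
    "fit_lm_arcsine",
    "METHODS",
]


@dataclass(frozen=True)
class ComparatorResult:
    method: str
    beta_hat: float
    se: float
    p_value: float
    converged: bool


def transform_log(y, T) -> np.ndarray:
    """log((y + 1) / T) relative-abundance transform."""
    y = np.asarray(y, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("total reads must be positive")
    if np.any(y < 0):
        raise DomainError("counts must be non-negative")
    return np.log((y + 1.0) / T)


def transform_arcsine(y, T) -> np.ndarray:
    """arcsin(sqrt(y / T)) variance-stabilizing transform, in [0, pi/2]."""
    y = np.asarray(y, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("total reads must be positive")
    if np.any(y < 0) or np.any(y > T):
        raise DomainError("counts must satisfy 0 <= y <= T")
    return np.arcsin(np.sqrt(y / T))


def _design(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.column_stack([np.ones(x.shape[0]), x])


def fit_nb_glm(y, T, x, control: FitControl | None = None) -> ComparatorResult:
    """NB regression log(mu) = log(T) + b0 + x*beta, no random effects.

    Fitted by the same IWLS machinery as the mixed model (alternating
    weighted least squares for beta with Newton updates of theta)."""
    model = NegativeBinomialMixedModel(
        endog=y, exog=_design(x), groups=None,
        offset=np.log(np.asarray(T, dtype=float)),
        exog_names=["Intercept", "x"])
    res = model.fit(control)
    stat, p = res.wald_test(1)
    return ComparatorResult("NB", float(res.params.iloc[1]),
                            float(res.bse.iloc[1]), p, res.converged)


def fit_lmm_transformed(y, T, x, groups, transform: str = "arcsine"
                        ) -> ComparatorResult:
    """Random-intercept LMM on the transformed relative abundance."""
    if transform == "log":
        resp = transform_log(y, T)
    elif transform == "arcsine":
        resp = transform_arcsine(y, T)
    else:
        raise DomainError(f"unknown transform {transform!r}")
    sol = fit_weighted_lmm(resp, _design(x), np.asarray(groups))
    se = float(np.sqrt(sol.beta_cov[1, 1]))
    if se < 1e-12:  # numerically constant response: no evidence either way
        return ComparatorResult(
            "LMM_log" if transform == "log" else "LMM_arcsine",
            float(sol.beta[1]), se, 1.0, True)
    stat = sol.beta[1] / se
    n, p = resp.shape[0], 2
    K = int(np.asarray(groups).max()) + 1
    df = n - p - max(K - 1, 0)
    pv = 2 * float(stats.t.sf(abs(stat), df)) if df > 0 else \
        2 * float(stats.norm.sf(abs(stat)))
    name = "LMM_log" if transform == "log" else "LMM_arcsine"
    return ComparatorResult(name, float(sol.beta[1]), se, min(pv, 1.0), True)


def fit_lm_arcsine(y, T, x) -> ComparatorResult:
    """OLS on arcsin(sqrt(y/T)) with a classical t-test for beta."""
    resp = transform_arcsine(y, T)
    sol = weighted_ls(resp, _design(x))
    se = float(np.sqrt(sol.beta_cov[1, 1]))
    if se < 1e-12:
        return ComparatorResult("LM", float(sol.beta[1]), se, 1.0, True)
    stat = sol.beta[1] / se
    df = resp.shape[0] - 2
    pv = min(2 * float(stats.t.sf(abs(stat), df)), 1.0)
    return ComparatorResult("LM", float(sol.beta[1]), se, pv, True)


def _fit_nbmm(y, T, x, groups, control=None) -> ComparatorResult:
    model = NegativeBinomialMixedModel(
        endog=y, exog=_design(x), groups=groups,
        offset=np.log(np.asarray(T, dtype=float)),
        exog_names=["Intercept", "x"])
    res = model.fit(control)
    _, p = res.wald_test(1)
    return ComparatorResult("NBMM", float(res.params.iloc[1]),
                            float(res.bse.iloc[1]), p, res.converged)


#: dispatch table used by the benchmark harness; every entry takes
#: (y, T, x, groups) and returns a ComparatorResult
METHODS = {
    "NBMM": lambda y, T, x, g: _fit_nbmm(y, T, x, g),
    "NB": lambda y, T, x, g: fit_nb_glm(y, T, x),
    "LMM_log": lambda y, T, x, g: fit_lmm_transformed(y, T, x, g, "log"),
    "LMM_arcsine": lambda y, T, x, g: fit_lmm_transformed(y, T, x, g, "arcsine"),
    "LM": lambda y, T, x, g: fit_lm_arcsine(y, T, x),
}
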