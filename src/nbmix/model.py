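"""Negative binomial mixed model (NBMM) for clustered sequencing counts.

The model for a single count feature y over n samples is

    y_i ~ NB(mu_i, theta),
    log(mu_i) = offset_i + X_i beta + b_{g(i)},    b ~ N_K(0, tau^2 I)

where the offset is normally log(T_i), the log total reads of sample i,
X holds host factors (with intercept) and g assigns each sample to one of
K groups (litter, dam, family, ...).  Fitting is by iterative weighted
least squares (IWLS, a penalized quasi-likelihood scheme): at the current
parameters the NB log-likelihood is replaced by a weighted normal
approximation with pseudo-response t and pseudo-weights w, the surrogate
weighted LMM

    t_i = offset_i + X_i beta + b_{g(i)} + w_i^{-1/2} e_i,  e ~ N(0, sigma^2 I)

is refitted by REML, and theta is updated by Newton-Raphson on its
profile likelihood.  The surrogate's free residual variance sigma^2
absorbs residual over-dispersion when theta is poorly estimated.

Convergence uses the relative-change criterion on the summed linear
predictor, (S_j - S_{j-1})^2 < tol * S_j^2 with S_j = sum_i eta_i^{(j)},
plus a safeguard on the max absolute per-sample change in eta (the sum
alone can cancel).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import family
from .exceptions import DegenerateFeatureError, DomainError, RankDeficientError
from .lmm import LMMSolution, fit_weighted_lmm, weighted_ls

__all__ = ["FitControl", "NegativeBinomialMixedModel", "NBMMResults"]


@dataclass
class FitControl:
    """Tuning knobs of the IWLS fit.

    tol : relative-change convergence epsilon on the summed linear
        predictor (default 1e-5).
    eta_tol : safeguard bound on max |delta eta_i| per sample (the summed
        criterion can cancel across samples).
    max_iter : IWLS iteration cap; hitting it reports converged=False,
        it never raises.
    theta_bounds : clamp interval for the shape parameter; the profile
        MLE of theta is fragile and sigma^2 absorbs the slack.
    theta_fixed : if set, theta is held at this value (Poisson-limit and
        reduction tests use this).
    tau2_zero : pin the random-effect variance at zero (pure fixed-effect
        weighted fit).
    scoring : pseudo-data flavour — "fisher" (default) uses the expected
        information working data (w = mu*theta/(mu+theta),
        t = eta + (y-mu)/mu), for which Var(t|eta) = 1/w holds exactly
        and Wald tests are near-ML efficient; "observed" uses the exact
        second derivative (w = -L'').
    """

    tol: float = 1e-5
    max_iter: int = 50
    theta_bounds: tuple[float, float] = (1e-2, 1e4)
    theta_init: float = 1.0
    eta_tol: float = 1e-4
    weight_floor: float = family.WEIGHT_FLOOR
    theta_fixed: float | None = None
    tau2_zero: bool = False
    scoring: str = "fisher"
    verbose: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.theta_bounds
        if self.tol <= 0 or self.max_iter < 1 or not (0 < lo < hi):
            raise DomainError("invalid fit control settings")


class NegativeBinomialMixedModel:
    """NB mixed model for one count feature.

    Parameters
    ----------
    endog : (n,) non-negative integer counts.
    exog : (n, p) fixed-effect design including the intercept column.
    groups : (n,) group labels for the random intercept, or None for a
        pure fixed-effects NB regression.
    offset : (n,) known offset on the log-mean scale, normally
        ``log(total_reads)``; defaults to zero.
    """

    def __init__(self, endog, exog, groups=None, offset=None, exog_names=None):
        y = np.asarray(endog)
        self.endog = family._check_counts(y).astype(np.int64)
        n = self.endog.shape[0]
        if np.all(self.endog == 0) or np.sum(self.endog > 0) <= 1:
            raise DegenerateFeatureError(
                "degenerate feature: needs at least two positive counts")
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise DomainError("exog/endog length mismatch")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficientError("fixed-effect design is rank deficient")
        self.exog = X
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(X.shape[1])])
        self.offset = (np.zeros(n) if offset is None
                       else np.asarray(offset, dtype=float))
        if self.offset.shape[0] != n or np.any(~np.isfinite(self.offset)):
            raise DomainError("offset must be finite, length n")
        if groups is None:
            self.groups = None
            self.group_labels = []
            self.k_groups = 0
        else:
            codes, labels = pd.factorize(np.asarray(groups), sort=True)
            if len(labels) < 1 or codes.shape[0] != n:
                raise DomainError("invalid groups")
            self.groups = codes
            self.group_labels = list(labels)
            self.k_groups = len(labels)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, fixed,
                       group: str | None = None,
                       total_reads: str | None = None):
        """Build the model from a tidy per-sample data frame.

        Categorical columns in ``fixed`` are expanded to treatment-coded
        indicators (reference = first level in sort order).  When
        ``total_reads`` names a column, its log becomes the offset.
        """
        fixed = [fixed] if isinstance(fixed, str) else list(fixed)
        cols = [pd.Series(1.0, index=data.index, name="Intercept")]
        for name in fixed:
            col = data[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.astype(float))
            else:
                dummies = pd.get_dummies(col.astype("category"), prefix=name,
                                         drop_first=True, dtype=float)
                cols.extend(dummies[c] for c in dummies.columns)
        X = pd.concat(cols, axis=1)
        offset = None
        if total_reads is not None:
            T = data[total_reads].to_numpy(dtype=float)
            if np.any(T <= 0):
                raise DomainError("total reads must be positive")
            offset = np.log(T)
        return cls(endog=data[response].to_numpy(), exog=X.to_numpy(),
                   groups=None if group is None else data[group].to_numpy(),
                   offset=offset, exog_names=list(X.columns))

    def fit(self, control: FitControl | None = None) -> "NBMMResults":
        """Run the IWLS algorithm; never raises on non-convergence."""
        control = control or FitControl()
        y, X, offset = self.endog, self.exog, self.offset
        n, p = X.shape
        use_re = self.groups is not None and not control.tau2_zero

        # init: least squares of log((y+0.5)) - offset on X; b = 0
        z0 = np.log(y + 0.5) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
        b = np.zeros(self.k_groups)
        theta = (control.theta_fixed if control.theta_fixed is not None
                 else control.theta_init)

        eta = offset + X @ beta + (b[self.groups] if use_re else 0.0)
        S_prev = float(np.sum(eta))
        trace: list[dict] = []
        converged = False
        sol: LMMSolution | None = None
        for it in range(1, control.max_iter + 1):
            pseudo = family.compute_pseudo_data(y, eta, theta,
                                                weight_floor=control.weight_floor,
                                                scoring=control.scoring)
            if use_re:
                sol = fit_weighted_lmm(pseudo.t, X, self.groups, weights=pseudo.w,
                                       offset=offset, n_groups=self.k_groups)
                b = sol.b
            else:
                sol = weighted_ls(pseudo.t, X, w=pseudo.w, offset=offset)
            beta = sol.beta
            eta_new = sol.fitted if use_re else offset + X @ beta
            mu = np.exp(np.clip(eta_new, -30.0, 30.0))
            if control.theta_fixed is None:
                theta = family.update_theta(y, mu, theta_init=theta,
                                            bounds=control.theta_bounds)
            S = float(np.sum(eta_new))
            max_delta = float(np.max(np.abs(eta_new - eta)))
            trace.append({"iter": it, "eta_sum": S, "max_delta_eta": max_delta,
                          "theta": theta, "tau2": sol.tau2, "sigma2": sol.sigma2})
            if control.verbose:
                print(f"iter {it}: sum(eta)={S:.6f} max|d eta|={max_delta:.2e} "
                      f"theta={theta:.4f} tau2={sol.tau2:.4f}")
            eta = eta_new
            if ((S - S_prev) ** 2 < control.tol * S**2
                    and max_delta < control.eta_tol):
                converged = True
                break
            S_prev = S
        return NBMMResults(self, sol, theta=theta, converged=converged,
                           n_iter=len(trace), trace=trace, control=control)


class NBMMResults:
    """Fit results: estimates, uncertainties and Wald tests.

    Wald tests of H0: beta_k = 0 use the fixed-effect covariance of the
    final surrogate LMM with a t reference on
    ``df = n - p - (K - 1)`` degrees of freedom (containment-style), or
    the normal when df <= 0.
    """

    def __init__(self, model, sol: LMMSolution, theta, converged, n_iter,
                 trace, control):
        self.model = model
        self._sol = sol
        names = model.exog_names
        self.params = pd.Series(sol.beta, index=names)
        self.bse = pd.Series(np.sqrt(np.diag(sol.beta_cov)), index=names)
        self.cov_params = pd.DataFrame(sol.beta_cov, index=names, columns=names)
        self.random_effects = pd.Series(
            sol.b, index=model.group_labels[: sol.b.shape[0]])
        self.tau2 = float(sol.tau2)
        self.sigma2 = float(sol.sigma2)
        self.theta = float(theta)
        self.tau2_boundary = bool(sol.boundary)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.trace = trace
        self.control = control
        n, p = model.exog.shape
        k = model.k_groups
        self.df_resid = n - p - max(k - 1, 0)
        stats_p = [self.wald_test(j) for j in range(p)]
        self.tvalues = pd.Series([s for s, _ in stats_p], index=names)
        self.pvalues = pd.Series([pv for _, pv in stats_p], index=names)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fitted means mu_i on the count scale."""
        eta = self._sol.fitted if self._sol.fitted is not None else (
            self.model.offset + self.model.exog @ self.params.to_numpy())
        return np.exp(np.clip(eta, -30, 30))

    def wald_test(self, coef) -> tuple[float, float]:
        """Wald statistic and two-sided p-value for H0: beta_k = 0."""
        if isinstance(coef, str):
            coef = self.model.exog_names.index(coef)
        if not 0 <= coef < len(self.params):
            raise DomainError(f"no coefficient at index {coef}")
        se = self.bse.iloc[coef]
        if se == 0 or not np.isfinite(se):
            raise DomainError(
                f"zero standard error for coefficient "
                f"{self.model.exog_names[coef]}")
        stat = float(self.params.iloc[coef] / se)
        if self.df_resid > 0:
            p = 2.0 * float(stats.t.sf(abs(stat), self.df_resid))
        else:
            p = 2.0 * float(stats.norm.sf(abs(stat)))
        return stat, min(max(p, 0.0), 1.0)

    def summary(self) -> str:
        coef = pd.DataFrame({
            "coef": self.params, "std err": self.bse,
            "t": self.tvalues, "P>|t|": self.pvalues,
        })
        lines = [
            "Negative Binomial Mixed Model (IWLS/PQL)",
            "=" * 56,
            f"No. samples: {self.model.exog.shape[0]}    "
            f"groups: {self.model.k_groups}    df resid: {self.df_resid}",
            f"converged: {self.converged} in {self.n_iter} iterations",
            coef.to_string(float_format=lambda v: f"{v: .4f}"),
            "-" * 56,
            f"theta (shape): {self.theta:.4f}    tau^2: {self.tau2:.4f}    "
            f"sigma^2: {self.sigma2:.4f}",
        ]
        if self.tau2_boundary:
            lines.append("note: variance-ratio estimate at search boundary")
        return "\n".join(lines)

    def to_json(self, path=None):
        """Serialize estimates plus full provenance (control, trace)."""
        payload = {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "random_effects": {str(k): v for k, v in
                               self.random_effects.to_dict().items()},
            "tau2": self.tau2, "sigma2": self.sigma2, "theta": self.theta,
            "converged": self.converged, "n_iter": self.n_iter,
            "df_resid": self.df_resid,
            "control": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(self.control).items()},
            "trace": self.trace,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
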