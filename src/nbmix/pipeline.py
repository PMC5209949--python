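"""Per-feature association screening over a count table.

Reads a feature-by-sample count TSV plus a per-sample metadata TSV,
fits the NB mixed model (and optionally the comparators) to every
feature with a log total-reads offset and a grouping random intercept,
and writes a tidy, ranked results table — the standard differential
abundance screen for clustered designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .comparators import fit_lm_arcsine, fit_lmm_transformed, fit_nb_glm
from .exceptions import AlignmentError, DomainError, NBMixError
from .model import FitControl, NegativeBinomialMixedModel

__all__ = ["CountMatrix", "read_count_table", "screen_features",
           "write_results", "read_results"]

TOTAL_READS_ID = "total_reads"


@dataclass
class CountMatrix:
    """Feature x sample counts plus per-sample total reads."""

    counts: pd.DataFrame          # features (rows) x samples (columns)
    total_reads: pd.Series        # indexed by sample

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise DomainError("duplicated feature identifiers")
        if self.counts.columns.duplicated().any():
            raise DomainError("duplicated sample identifiers")
        if not self.total_reads.index.equals(self.counts.columns):
            raise AlignmentError("total reads do not align with samples")
        if (self.total_reads <= 0).any():
            raise DomainError("total reads must be positive")
        per_sample_max = self.counts.max(axis=0)
        if (self.total_reads < per_sample_max).any():
            offenders = self.total_reads.index[
                self.total_reads < per_sample_max].tolist()
            raise DomainError(
                f"total reads below max feature count for samples {offenders}")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def read_count_table(path, samples_as_rows: bool = False) -> CountMatrix:
    """Load a count TSV (features as rows by default).

    A row (or column, under ``samples_as_rows``) with identifier
    ``total_reads`` supplies the per-sample totals; otherwise totals
    default to the per-sample column sums (logged in the object).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples_as_rows:
        df = df.T
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            cell = df.index[bad.to_numpy()][0]
            raise DomainError(
                f"invalid count at feature {cell!r}, sample {col!r}: "
                f"{df.loc[cell, col]!r}")
        df[col] = vals.astype(np.int64)
    if TOTAL_READS_ID in df.index:
        totals = df.loc[TOTAL_READS_ID].astype(np.int64)
        counts = df.drop(index=TOTAL_READS_ID)
    else:
        counts = df
        totals = df.sum(axis=0).astype(np.int64)
    return CountMatrix(counts=counts, total_reads=totals)


def _align_metadata(cm: CountMatrix, meta: pd.DataFrame,
                    sample_col: str | None = None) -> pd.DataFrame:
    meta = meta.set_index(sample_col) if sample_col else meta
    missing = [s for s in cm.counts.columns if s not in meta.index]
    if missing or meta.index.duplicated().any():
        raise AlignmentError(
            f"metadata misaligned; missing samples: {missing}, "
            f"duplicated: {meta.index[meta.index.duplicated()].tolist()}")
    return meta.loc[cm.counts.columns]


def _expand_fixed(meta: pd.DataFrame, fixed) -> pd.DataFrame:
    fixed = [fixed] if isinstance(fixed, str) else list(fixed)
    cols = [pd.Series(1.0, index=meta.index, name="Intercept")]
    for name in fixed:
        col = meta[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col.astype("category"), prefix=name,
                                     drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
    return pd.concat(cols, axis=1)


def screen_features(cm: CountMatrix, meta: pd.DataFrame, fixed,
                    random: str | None, methods=("NBMM",),
                    alpha: float = 0.05, control: FitControl | None = None,
                    min_prevalence: int = 0,
                    sample_col: str | None = None) -> pd.DataFrame:
    """Fit each requested method to every feature; one row per
    feature x method x tested coefficient.

    Features with fewer than two positive counts (or below
    ``min_prevalence`` positive samples) are reported with status
    "skipped: degenerate" rather than fitted.  The Benjamini-Hochberg
    adjusted p-value is added per method across features.
    """
    meta = _align_metadata(cm, meta, sample_col)
    X = _expand_fixed(meta, fixed)
    coef_names = [c for c in X.columns if c != "Intercept"]
    if random is not None:
        groups = meta[random].to_numpy()
        if pd.unique(groups).shape[0] < 2:
            raise DomainError("grouping variable needs >= 2 levels")
    else:
        groups = None
    T = cm.total_reads.to_numpy(dtype=float)
    logT = np.log(T)
    x_primary = X[coef_names[0]].to_numpy() if coef_names else None

    rows = []
    for feat in cm.counts.index:
        y = cm.counts.loc[feat].to_numpy()
        n_pos = int((y > 0).sum())
        if n_pos <= 1 or n_pos < min_prevalence:
            for method in methods:
                rows.append({"feature": feat, "method": method,
                             "coef": coef_names[0] if coef_names else "",
                             "status": "skipped: degenerate"})
            continue
        for method in methods:
            try:
                rows.extend(_fit_one(feat, method, y, T, logT, X, coef_names,
                                     groups, meta, random, control))
            except NBMixError as exc:
                rows.append({"feature": feat, "method": method,
                             "coef": coef_names[0] if coef_names else "",
                             "status": f"failed: {exc}"})
    out = pd.DataFrame(rows)
    out["significant"] = out.get("p_value", pd.Series(dtype=float)) < alpha
    out["p_adj"] = np.nan
    for method in out["method"].unique():
        for coef in out.loc[out["method"] == method, "coef"].unique():
            mask = ((out["method"] == method) & (out["coef"] == coef)
                    & out["p_value"].notna())
            if mask.any():
                out.loc[mask, "p_adj"] = multipletests(
                    out.loc[mask, "p_value"], method="fdr_bh")[1]
    order = ["feature", "method", "coef", "beta_hat", "se", "p_value",
             "p_adj", "significant", "converged", "theta_hat", "tau2_hat",
             "sigma2_hat", "status"]
    return out.reindex(columns=order)


def _fit_one(feat, method, y, T, logT, X, coef_names, groups, meta, random,
             control):
    rows = []
    if method == "NBMM":
        model = NegativeBinomialMixedModel(
            endog=y, exog=X.to_numpy(), groups=groups, offset=logT,
            exog_names=list(X.columns))
        res = model.fit(control)
        for coef in coef_names:
            _, p = res.wald_test(coef)
            rows.append({"feature": feat, "method": method, "coef": coef,
                         "beta_hat": float(res.params[coef]),
                         "se": float(res.bse[coef]), "p_value": p,
                         "converged": res.converged, "theta_hat": res.theta,
                         "tau2_hat": res.tau2, "sigma2_hat": res.sigma2,
                         "status": "ok"})
        return rows
    x = X[coef_names[0]].to_numpy()
    if method == "NB":
        r = fit_nb_glm(y, T, x, control)
    elif method in ("LMM_log", "LMM_arcsine"):
        codes = pd.factorize(groups, sort=True)[0]
        r = fit_lmm_transformed(y, T, x, codes,
                                "log" if method == "LMM_log" else "arcsine")
    elif method == "LM":
        r = fit_lm_arcsine(y, T, x)
    else:
        raise DomainError(f"unknown method {method!r}")
    rows.append({"feature": feat, "method": method, "coef": coef_names[0],
                 "beta_hat": r.beta_hat, "se": r.se, "p_value": r.p_value,
                 "converged": r.converged, "status": "ok"})
    return rows


def write_results(table: pd.DataFrame, path, provenance: dict | None = None
                  ) -> None:
    """Write the results TSV with a '#'-prefixed provenance header."""
    header = {"nbmix_version": __version__}
    header.update(provenance or {})
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"# {key}: {val}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
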