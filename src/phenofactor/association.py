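"""Downstream regression contracts for factor scores.

Factor scores as the *outcome* use weighted least squares with the
per-pattern inverse-variance weights (scores are heteroskedastic across
missingness patterns by construction). Factor scores as a *predictor*
use Huber–White ("HC0") sandwich standard errors, linear or logistic.
P values come from the normal approximation, consistent with large-n
biobank practice. Nuisance covariates are always part of the design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class AssociationResult:
    """Long-format estimates for the terms of one regression."""

    table: pd.DataFrame  # term, estimate, se, stat, p
    n_used: int
    family: str = "linear"
    incremental_r2: float | None = None
    flags: list[str] | None = None

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def _result_frame(names, params, se) -> pd.DataFrame:
    stat = params / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {"term": names, "estimate": params, "se": se, "stat": stat,
         "p": np.clip(p, np.finfo(float).tiny, 1.0)}
    )


def _design(predictors: np.ndarray | None, covariates: np.ndarray | None,
            names_pred: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(0)]
    blocks, names = [], ["intercept"]
    if predictors is not None:
        predictors = np.atleast_2d(np.asarray(predictors, float))
        if predictors.shape[0] == 1 and predictors.shape[1] > 1:
            predictors = predictors.T
        blocks.append(predictors)
        names += names_pred or [f"x{j}" for j in range(predictors.shape[1])]
    if covariates is not None and np.asarray(covariates).size:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] == 1 and covariates.shape[1] > 1:
            covariates = covariates.T
        blocks.append(covariates)
        names += [f"cov{j}" for j in range(covariates.shape[1])]
    n = blocks[0].shape[0]
    X = np.column_stack([np.ones(n)] + blocks)
    return X, names


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")


def wls_regress(
    scores: np.ndarray,
    weights: np.ndarray,
    predictors: np.ndarray,
    covariates: np.ndarray | None = None,
    included: np.ndarray | None = None,
    predictor_names: list[str] | None = None,
) -> AssociationResult:
    """WLS of factor scores on predictors with inverse-variance weights.

    Rows with ``included == False`` or any missing value never enter the
    fit. With all weights equal the estimates coincide with OLS.
    """
    y = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    X, names = _design(predictors, covariates, predictor_names)
    keep = np.isfinite(y) & np.isfinite(w) & np.all(np.isfinite(X), axis=1)
    if included is not None:
        keep &= np.asarray(included, dtype=bool)
    y, w, X = y[keep], w[keep], X[keep]
    _check_rank(X)
    res = sm.WLS(y, X, weights=w).fit(use_t=False)
    return AssociationResult(
        table=_result_frame(names, res.params, res.bse),
        n_used=int(keep.sum()),
        family="linear",
    )


def robust_regress(
    outcome: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "linear",
    included: np.ndarray | None = None,
    predictor_names: list[str] | None = None,
) -> AssociationResult:
    """Regression of an outcome on factor scores with HC0 sandwich SEs.

    ``family="linear"`` fits OLS, ``"logistic"`` a binomial GLM; both use
    the Huber–White HC0 covariance with normal-approximation p values.
    Perfect separation in the logistic fit is flagged and no estimate is
    returned for the affected model.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _design(scores, covariates, predictor_names or ["score"])
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if included is not None:
        keep &= np.asarray(included, dtype=bool)
    y, X = y[keep], X[keep]
    _check_rank(X)
    if family == "linear":
        res = sm.OLS(y, X).fit(cov_type="HC0", use_t=False)
        params, se = res.params, res.bse
    elif family == "logistic":
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        try:
            with np.errstate(all="ignore"):
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        except PerfectSeparationError:
            return AssociationResult(
                table=pd.DataFrame(columns=["term", "estimate", "se", "stat", "p"]),
                n_used=int(keep.sum()),
                family=family,
                flags=["perfect_separation"],
            )
        params, se = res.params, res.bse
        if np.any(np.abs(params) > 1e2) or not np.all(np.isfinite(se)):
            return AssociationResult(
                table=pd.DataFrame(columns=["term", "estimate", "se", "stat", "p"]),
                n_used=int(keep.sum()),
                family=family,
                flags=["separation_suspected"],
            )
    else:
        raise ValueError(f"unknown family {family!r}")
    return AssociationResult(
        table=_result_frame(names, np.asarray(params), np.asarray(se)),
        n_used=int(keep.sum()),
        family=family,
    )


def _r2(y: np.ndarray, X: np.ndarray, family: str) -> float:
    if family == "linear":
        res = sm.OLS(y, X).fit()
        return float(res.rsquared)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    n = y.shape[0]
    llf, llnull = float(res.llf), float(res.llnull)
    cs = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    denom = 1.0 - np.exp(2.0 * llnull / n)
    return float(cs / denom)


def incremental_r2(
    outcome: np.ndarray,
    base_design: np.ndarray,
    added_terms: np.ndarray,
    family: str = "linear",
    n_bootstrap: int = 0,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """ΔR² (linear) or Δ Nagelkerke pseudo-R² (logistic) of added terms.

    The base and augmented models share rows exactly; rows with missing
    values in either part are dropped from both. An optional bootstrap
    gives a percentile confidence interval.
    """
    y = np.asarray(outcome, dtype=float)
    base = np.atleast_2d(np.asarray(base_design, dtype=float))
    if base.shape[0] != y.shape[0]:
        base = base.T
    added = np.atleast_2d(np.asarray(added_terms, dtype=float))
    if added.shape[0] != y.shape[0]:
        added = added.T
    if base.shape[0] != y.shape[0] or added.shape[0] != y.shape[0]:
        raise ValueError("models are not nested on identical rows")
    keep = (
        np.isfinite(y)
        & np.all(np.isfinite(base), axis=1)
        & np.all(np.isfinite(added), axis=1)
    )
    y, base, added = y[keep], base[keep], added[keep]
    n = y.shape[0]
    Xb = np.column_stack([np.ones(n), base])
    Xa = np.column_stack([Xb, added])

    if np.linalg.matrix_rank(Xa) == np.linalg.matrix_rank(Xb):
        delta = 0.0  # added terms add no column space (e.g. constants)
    else:
        delta = _r2(y, Xa, family) - _r2(y, Xb, family)
    out = {"delta_r2": float(delta), "n_used": int(n), "family": family}

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            yb, Xbb, Xab = y[idx], Xb[idx], Xa[idx]
            try:
                draws[b] = _r2(yb, Xab, family) - _r2(yb, Xbb, family)
            except Exception:
                draws[b] = np.nan
        alpha = (1.0 - ci_level) / 2.0
        good = draws[np.isfinite(draws)]
        out["ci"] = (
            float(np.quantile(good, alpha)),
            float(np.quantile(good, 1.0 - alpha)),
        )
        out["n_bootstrap"] = int(n_bootstrap)
    return out


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Bonferroni-adjusted significance across a family of outcomes."""
    p = np.asarray(p_values, dtype=float)
    cutoff = alpha / p.size
    return p < cutoff, cutoff
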