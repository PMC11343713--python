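"""Confirmatory factor analysis by diagonally weighted least squares.

The sparsified orthogonal factor model fixes which loadings are free (the
pattern from the EFA) and minimizes

    F(Λ) = Σ_{a<b} w_ab (s_ab − (ΛΛ')_ab)²

over the free loadings, where w_ab is the inverse of the per-observation
asymptotic variance of the correlation estimate for pair (a, b) — delta
method for Pearson pairs, inverse observed information for
polychoric/polyserial pairs. Uniquenesses are derived from the
unit-diagonal constraint ψ_jj = 1 − Σ_t λ_jt², so factors stay orthogonal
with unit variance and the diagonal fits exactly.

Negative derived uniquenesses (Heywood cases) raise, and
:func:`prune_heywood` iteratively removes the worst offender until the
model is clean — dropping factors that lose identifiability along the
way. Fit indices use the uncorrected discrepancy-based chi-square
(``n·F_min``); no scale-shifted ("WLSMV"-style) correction is applied,
and indices are labelled accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .correlations import MixedCorrelation
from .efa import FactorModel

DWLS_TOL = 1e-8
DWLS_MAX_ITER = 500


class HeywoodError(RuntimeError):
    """Raised when derived uniquenesses go negative.

    Carries the offending item indices, the fitted (flagged) model, and
    the uniqueness values so callers can prune and refit.
    """

    def __init__(self, items, model, psi):
        super().__init__(f"negative residual variance for items {list(items)}")
        self.items = list(items)
        self.model = model
        self.psi = psi


@dataclass
class FitIndices:
    """Discrepancy-based global fit summary (uncorrected DWLS scaling)."""

    chi_square: float
    df: int
    rmsea: float
    srmr: float
    cfi: float
    tli: float
    n_used: int

    def as_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "cfi": self.cfi,
            "tli": self.tli,
            "n_used": self.n_used,
        }


def _weights_from_corr(corr) -> tuple[np.ndarray, np.ndarray, int]:
    """(S, W, n) with W the per-pair DWLS weights, zero on the diagonal."""
    if isinstance(corr, MixedCorrelation):
        S = np.where(np.isnan(corr.matrix), 0.0, corr.matrix)
        v = corr.pair_var.copy()
        n = int(corr.n) if corr.n else int(np.max(corr.pair_n))
    else:
        S = np.asarray(corr, dtype=float)
        v = (1.0 - S**2) ** 2
        n = 0
    bad = ~np.isfinite(v) | (v <= 0)
    if bad.any():
        v = np.where(bad, np.nanmedian(v[~bad]) if (~bad).any() else 1.0, v)
    W = 1.0 / v
    np.fill_diagonal(W, 0.0)
    return S, W, n


def _pack(lam: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    return lam[pattern]


def _unpack(theta: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    lam = np.zeros(pattern.shape)
    lam[pattern] = theta
    return lam


def dwls_discrepancy(S: np.ndarray, W: np.ndarray, lam: np.ndarray) -> float:
    resid = S - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return 0.5 * float(np.sum(W * resid**2))


def dwls_fit(
    corr,
    pattern: np.ndarray,
    n: int | None = None,
    start: np.ndarray | None = None,
    on_heywood: str = "raise",
) -> FactorModel:
    """Fit the orthogonal factor model by DWLS over the free loadings.

    ``pattern`` is the boolean p×t free-loading map; ``start`` supplies
    starting loadings (typically the rotated EFA solution), defaulting to
    0.5 on free entries. ``on_heywood`` is ``"raise"`` (default) or
    ``"flag"``.
    """
    pattern = np.asarray(pattern, dtype=bool)
    S, W, n_corr = _weights_from_corr(corr)
    if n is None:
        n = n_corr
    p, t = pattern.shape
    if S.shape[0] != p:
        raise ValueError("pattern rows must match correlation dimension")
    labels = (
        corr.item_labels
        if isinstance(corr, MixedCorrelation)
        else [f"item{j:03d}" for j in range(p)]
    )
    weak = np.flatnonzero(pattern.sum(axis=0) < 3).tolist()
    if weak:
        warnings.warn(f"factors {weak} have fewer than 3 free items", stacklevel=2)

    if start is None:
        lam0 = np.where(pattern, 0.5, 0.0)
    else:
        lam0 = np.where(pattern, np.asarray(start, dtype=float), 0.0)
    theta0 = _pack(lam0, pattern)

    def objective(theta: np.ndarray):
        lam = _unpack(theta, pattern)
        resid = lam @ lam.T - S
        np.fill_diagonal(resid, 0.0)
        f = 0.5 * float(np.sum(W * resid**2))
        grad_full = 2.0 * (W * resid) @ lam
        return f, grad_full[pattern]

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": DWLS_MAX_ITER, "ftol": DWLS_TOL * 1e-4, "gtol": 1e-10},
    )
    if not res.success and "ITERATIONS" in str(res.message).upper():
        raise RuntimeError(f"DWLS failed to converge: {res.message} after {res.nit} iterations")
    lam = _unpack(res.x, pattern)
    psi = 1.0 - np.sum(lam**2, axis=1)
    heywood = psi <= 0
    model = FactorModel(
        loadings=lam,
        uniquenesses=np.where(heywood, np.nan, psi),
        item_labels=list(labels),
        provenance="cfa",
        heywood_flags=heywood,
        discrepancy=float(res.fun),
        n_iterations=int(res.nit),
    )
    if heywood.any() and on_heywood == "raise":
        raise HeywoodError(np.flatnonzero(heywood), model, psi)
    if not heywood.any():
        model.uniquenesses = psi
    return model


def prune_heywood(
    corr,
    pattern: np.ndarray,
    n: int | None = None,
    start: np.ndarray | None = None,
    min_items_per_factor: int = 2,
) -> tuple[FactorModel, list[dict]]:
    """Iteratively remove Heywood items until the DWLS fit is clean.

    At each round the item with the most negative derived uniqueness is
    dropped and the model refit; factors left with fewer than
    ``min_items_per_factor`` free items are dropped with a logged reason.
    Returns the clean model (on the surviving items) and the removal log.
    """
    pattern = np.asarray(pattern, dtype=bool).copy()
    if isinstance(corr, MixedCorrelation):
        work = corr
        labels = list(corr.item_labels)
    else:
        work = np.asarray(corr, dtype=float)
        labels = [f"item{j:03d}" for j in range(pattern.shape[0])]
    start_lam = None if start is None else np.asarray(start, dtype=float).copy()
    log: list[dict] = []

    while True:
        # drop under-identified factors first
        weak = np.flatnonzero(pattern.sum(axis=0) < min_items_per_factor)
        if weak.size:
            for f in weak.tolist():
                log.append({"action": "drop_factor", "factor": int(f),
                            "reason": f"fewer than {min_items_per_factor} free items"})
                warnings.warn(f"factor {f} dropped: under-identified", stacklevel=2)
            keep_f = np.setdiff1d(np.arange(pattern.shape[1]), weak)
            pattern = pattern[:, keep_f]
            if start_lam is not None:
                start_lam = start_lam[:, keep_f]
            if pattern.shape[1] == 0:
                raise RuntimeError("all factors dropped during Heywood pruning")
        try:
            model = dwls_fit(work, pattern, n=n, start=start_lam, on_heywood="raise")
            return model, log
        except HeywoodError as err:
            psi = err.psi
            worst = int(min(err.items, key=lambda j: psi[j]))
            log.append({
                "action": "drop_item",
                "item": labels[worst],
                "reason": f"negative residual variance ({psi[worst]:.4f})",
            })
            keep = np.ones(pattern.shape[0], dtype=bool)
            keep[worst] = False
            keep_idx = np.flatnonzero(keep)
            pattern = pattern[keep]
            labels = [labels[j] for j in keep_idx]
            if start_lam is not None:
                start_lam = start_lam[keep]
            work = (
                work.subset(keep_idx)
                if isinstance(work, MixedCorrelation)
                else work[np.ix_(keep_idx, keep_idx)]
            )


def fit_indices(corr, model: FactorModel, n: int | None = None,
                free_pattern: np.ndarray | None = None) -> FitIndices:
    """Global fit indices from the DWLS discrepancy.

    chi-square is ``n·F_min`` with the uncorrected discrepancy; the
    baseline model is the zero-correlation model on the same pairs.
    RMSEA = sqrt(max(χ²−df, 0)/(df·(n−1))); SRMR is the r.m.s.
    off-diagonal residual correlation; CFI and TLI compare against the
    baseline in the usual way.
    """
    S, W, n_corr = _weights_from_corr(corr)
    if n is None:
        n = n_corr
    if n <= 1:
        raise ValueError("fit indices need the estimation sample size n")
    lam = model.loadings
    p = lam.shape[0]
    if S.shape[0] != p:
        raise ValueError("item sets of model and correlation matrix differ")
    if free_pattern is None:
        free_pattern = lam != 0.0
    n_free = int(np.asarray(free_pattern, bool).sum())
    n_pairs = p * (p - 1) // 2
    df = n_pairs - n_free
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    df_b = n_pairs

    f_min = dwls_discrepancy(S, W, lam)
    f_base = dwls_discrepancy(S, W, np.zeros_like(lam))
    chi2 = n * f_min
    chi2_b = n * f_base

    resid = S - lam @ lam.T
    off = resid[np.triu_indices(p, k=1)]
    srmr = float(np.sqrt(np.mean(off**2)))
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    ratio_b = chi2_b / df_b
    tli = 1.0 if ratio_b <= 1.0 else (ratio_b - chi2 / df) / (ratio_b - 1.0)
    return FitIndices(
        chi_square=float(chi2),
        df=int(df),
        rmsea=rmsea,
        srmr=srmr,
        cfi=float(cfi),
        tli=float(tli),
        n_used=int(n),
    )


def indices_from_chi_square(
    chi_square: float, df: int, n: int,
    chi_square_baseline: float | None = None, df_baseline: int | None = None,
    srmr: float = np.nan,
) -> FitIndices:
    """Fit indices from already-computed chi-square quantities.

    Useful when the discrepancies come from elsewhere; applies the same
    RMSEA/CFI/TLI arithmetic as :func:`fit_indices`.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    if chi_square_baseline is None:
        cfi = tli = np.nan
    else:
        denom = max(chi_square_baseline - df_baseline, chi_square - df, 0.0)
        cfi = 1.0 if denom == 0 else 1.0 - max(chi_square - df, 0.0) / denom
        ratio_b = chi_square_baseline / df_baseline
        tli = 1.0 if ratio_b <= 1.0 else (ratio_b - chi_square / df) / (ratio_b - 1.0)
    return FitIndices(
        chi_square=float(chi_square), df=int(df), rmsea=rmsea, srmr=srmr,
        cfi=float(cfi), tli=float(tli), n_used=int(n),
    )


def holdout_evaluate(
    model: FactorModel, corr_holdout, n_holdout: int,
    free_pattern: np.ndarray | None = None,
) -> FitIndices:
    """Fit indices of a fixed, previously fitted model in holdout data.

    No parameter is re-estimated; the training loadings are scored
    against the holdout correlation matrix. Item label sets must match.
    """
    if isinstance(corr_holdout, MixedCorrelation):
        if list(corr_holdout.item_labels) != list(model.item_labels):
            raise ValueError("holdout item set does not match the fitted model")
    return fit_indices(corr_holdout, model, n=n_holdout, free_pattern=free_pattern)
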