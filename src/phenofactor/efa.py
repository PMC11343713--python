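"""Exploratory factor analysis: diagnostics, MINRES extraction, varimax.

MINRES minimizes the sum of squared off-diagonal residuals of
``R − ΛΛ'`` by quasi-Newton optimization over the uniquenesses with an
analytic gradient (given Ψ, the optimal rank-t Λ is the truncated
eigendecomposition of R − Ψ). Rotation is varimax with Kaiser row
normalization, delegated to statsmodels' factor-rotation routines, with
deterministic sign fixing and ordering by variance explained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .correlations import MixedCorrelation, nearest_psd

PSI_FLOOR = 1e-4


def _as_matrix(corr) -> np.ndarray:
    if isinstance(corr, MixedCorrelation):
        return corr.matrix
    return np.asarray(corr, dtype=float)


@dataclass
class FactorModel:
    """Orthogonal factor model: loadings Λ, diagonal uniquenesses Ψ.

    ``heywood_flags`` marks items whose fitted communality reached 1
    (uniqueness at the numerical floor); such models are flagged rather
    than silently floored.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    item_labels: list[str]
    provenance: str = "efa"
    heywood_flags: np.ndarray | None = None
    discrepancy: float = np.nan
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.heywood_flags is None:
            self.heywood_flags = np.zeros(self.loadings.shape[0], dtype=bool)

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def t(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)

    def implied_corr(self) -> np.ndarray:
        sigma = self.loadings @ self.loadings.T
        np.fill_diagonal(sigma, 1.0)
        return sigma

    def variance_explained_per_factor(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=0)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"factor{t}" for t in range(self.t)]
        return pd.DataFrame(self.loadings, index=self.item_labels, columns=cols)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "item_labels": self.item_labels,
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "heywood_flags": np.asarray(self.heywood_flags).astype(bool).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def from_json(path) -> "FactorModel":
        with open(path) as fh:
            payload = json.load(fh)
        return FactorModel(
            loadings=np.asarray(payload["loadings"], dtype=float),
            uniquenesses=np.asarray(payload["uniquenesses"], dtype=float),
            item_labels=list(payload["item_labels"]),
            provenance=payload.get("provenance", "efa"),
            heywood_flags=np.asarray(payload.get("heywood_flags"), dtype=bool),
        )


@dataclass
class EigenDiagnostics:
    """Eigenvalue-based factor-count diagnostics."""

    eigenvalues: np.ndarray
    parallel_count: int
    kaiser_count: int
    null_quantiles: np.ndarray = field(default_factory=lambda: np.zeros(0))


def eigen_diagnostics(
    corr,
    n: int,
    n_null_reps: int = 50,
    seed: int = 0,
    method: str = "simulation",
    data: np.ndarray | None = None,
) -> EigenDiagnostics:
    """Scree eigenvalues, Kaiser count, and parallel analysis.

    Parallel analysis compares the observed eigenvalues rank-by-rank to
    the 95th percentile of eigenvalues of null correlation matrices at
    the same n and p, generated either from independent standard normals
    (``method="simulation"``, the default) or by permuting the columns of
    ``data`` independently (``method="permutation"``).
    """
    R = _as_matrix(corr)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    p = R.shape[0]
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)

    null_eigs = np.empty((n_null_reps, p))
    for rep in range(n_null_reps):
        if method == "simulation":
            X = rng.standard_normal((n, p))
        elif method == "permutation":
            if data is None:
                raise ValueError("permutation parallel analysis needs raw data")
            X = np.column_stack([rng.permutation(data[:, j]) for j in range(p)])
        else:
            raise ValueError(f"unknown parallel-analysis method {method!r}")
        Rn = np.corrcoef(X, rowvar=False)
        null_eigs[rep] = np.sort(np.linalg.eigvalsh(Rn))[::-1]
    q95 = np.quantile(null_eigs, 0.95, axis=0)
    parallel = int(np.argmin(eigenvalues > q95)) if not (eigenvalues > q95).all() else p
    return EigenDiagnostics(
        eigenvalues=eigenvalues,
        parallel_count=parallel,
        kaiser_count=int((eigenvalues > 1.0).sum()),
        null_quantiles=q95,
    )


def _minres_objective(psi: np.ndarray, R: np.ndarray, t: int):
    """Sum of squared trailing eigenvalues of R − diag(ψ) and its gradient."""
    A = R.copy()
    np.fill_diagonal(A, 1.0 - psi)
    vals, vecs = np.linalg.eigh(A)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    lam = vecs[:, :t] * np.sqrt(np.clip(vals[:t], 0.0, None))
    resid = A - lam @ lam.T
    f = float(np.sum(vals[t:] ** 2) + np.sum(np.clip(vals[:t], None, 0.0) ** 2))
    grad = -2.0 * np.diag(resid)
    return f, grad, lam


def minres_extract(corr, t: int, labels: list[str] | None = None,
                   max_iter: int = 1000) -> FactorModel:
    """MINRES factor extraction of ``t`` factors.

    Starts the uniquenesses at 1 − SMC and minimizes the off-diagonal
    residual sum of squares by L-BFGS-B with uniquenesses bounded below
    at a small floor; items whose uniqueness lands on the floor are
    flagged as Heywood cases.
    """
    R = _as_matrix(corr)
    p = R.shape[0]
    if t >= p:
        raise ValueError("number of factors must be below number of items")
    if labels is None:
        labels = corr.item_labels if isinstance(corr, MixedCorrelation) else [
            f"item{j:03d}" for j in range(p)
        ]
    R, _ = nearest_psd(np.where(np.isnan(R), 0.0, R))

    inv = np.linalg.inv(nearest_psd(R, 1e-4)[0])
    smc = 1.0 - 1.0 / np.diag(inv)
    psi0 = np.clip(1.0 - smc, PSI_FLOOR * 2, 1.0)

    res = minimize(
        lambda s: _minres_objective(s, R, t)[:2],
        psi0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(PSI_FLOOR, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.status != 0 and "ITERATIONS" in str(res.message).upper():
        raise RuntimeError(
            f"MINRES failed to converge in {max_iter} iterations: {res.message}"
        )
    psi = np.asarray(res.x)
    _, _, lam = _minres_objective(psi, R, t)
    heywood = psi <= PSI_FLOOR * 1.5

    order = np.argsort(-np.sum(lam**2, axis=0))
    lam = lam[:, order]
    # deterministic sign: largest-magnitude loading per factor positive
    for c in range(t):
        if lam[np.argmax(np.abs(lam[:, c])), c] < 0:
            lam[:, c] = -lam[:, c]

    return FactorModel(
        loadings=lam,
        uniquenesses=psi,
        item_labels=list(labels),
        provenance="efa",
        heywood_flags=heywood,
        discrepancy=float(res.fun),
        n_iterations=int(res.nit),
    )


def varimax_rotate(
    model: FactorModel, kaiser_normalize: bool = True
) -> tuple[FactorModel, np.ndarray]:
    """Varimax rotation of an unrotated EFA model.

    Returns the rotated model plus the full orthonormal transform R such
    that the output loadings equal ``Λ_in @ R`` (including the
    deterministic column sign fix and reordering by variance explained).
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    lam = model.loadings.copy()
    if lam.shape[1] == 1:
        return model, np.eye(1)
    h = np.sqrt(np.sum(lam**2, axis=1))
    scale = np.where(h > 0, h, 1.0)
    work = lam / scale[:, None] if kaiser_normalize else lam
    with np.errstate(divide="ignore"):  # statsmodels logs log10 of exact zeros
        _, T = rotate_factors(work, "varimax")
    rotated = lam @ T

    order = np.argsort(-np.sum(rotated**2, axis=0))
    signs = np.ones(len(order))
    for c_out, c_in in enumerate(order):
        col = rotated[:, c_in]
        if col[np.argmax(np.abs(col))] < 0:
            signs[c_out] = -1.0
    perm = np.zeros((model.t, model.t))
    for c_out, c_in in enumerate(order):
        perm[c_in, c_out] = signs[c_out]
    R = T @ perm
    out = FactorModel(
        loadings=lam @ R,
        uniquenesses=model.uniquenesses.copy(),
        item_labels=list(model.item_labels),
        provenance=model.provenance,
        heywood_flags=np.asarray(model.heywood_flags).copy(),
        discrepancy=model.discrepancy,
    )
    return out, R


def efa_fit_stats(corr, model: FactorModel, n: int | None = None) -> dict:
    """Root-mean-square off-diagonal residual and variance explained."""
    R = _as_matrix(corr)
    resid = R - model.loadings @ model.loadings.T
    off = resid[~np.eye(model.p, dtype=bool)]
    off = off[~np.isnan(off)]
    return {
        "rms_residual": float(np.sqrt(np.mean(off**2))),
        "variance_explained": float(np.sum(model.loadings**2) / model.p),
    }


def pca_components(corr, t: int) -> np.ndarray:
    """Top-t principal component loadings (eigenvectors × √eigenvalue)."""
    R = _as_matrix(corr)
    vals, vecs = np.linalg.eigh(R)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    comp = vecs[:, :t] * np.sqrt(np.clip(vals[:t], 0.0, None))
    for c in range(t):
        if comp[np.argmax(np.abs(comp[:, c])), c] < 0:
            comp[:, c] = -comp[:, c]
    return comp


def threshold_pattern(model: FactorModel, cutoff: float = 0.1) -> tuple[np.ndarray, list[int]]:
    """Free-loading sparsity pattern: |λ| strictly greater than ``cutoff``.

    Returns the boolean p×t pattern and the indices of items dropped for
    having no surviving loading. Warns if a factor retains fewer than 3
    items (weak identifiability).
    """
    pattern = np.abs(model.loadings) > cutoff
    dropped = np.flatnonzero(~pattern.any(axis=1)).tolist()
    per_factor = pattern.sum(axis=0)
    weak = np.flatnonzero(per_factor < 3).tolist()
    if weak:
        warnings.warn(
            f"factors {weak} retain fewer than 3 items at cutoff {cutoff}",
            stacklevel=2,
        )
    return pattern, dropped
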