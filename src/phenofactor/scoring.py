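"""Factor scoring with categorical-item and missingness adjustments.

Scores are weighted sums of an individual's observed items,
``f̂_it = Σ_j a_jt x_ij``, with coefficients from either

* Bartlett (conditionally unbiased; the dependent-variable estimator):
  ``A_B = Ψ⁻¹Λ (Λ'Ψ⁻¹Λ)⁻¹``, or
* Thomson–Thurstone / regression (minimum MSE; the independent-variable
  estimator): ``A_TT = Ψ⁻¹Λ (I + Λ'Ψ⁻¹Λ)⁻¹``,

evaluated on the observed-item subset of each missingness pattern.

Categorical items enter through their residual expected latent values
(the ordered-probit posterior mean minus the covariate prediction), with
loadings and uniquenesses rescaled for the attenuation between the
categorical observation and the latent variable:

    λ*_jt = λ̂_jt · sqrt(var(x_j|z)) · Σ_τ φ(τ) / σ_x
    ψ*_jj = var(x_j|z) · (1 − (1 − ψ_jj) · (Σ_τ φ(τ))² / σ_x²)

where Σ_τ φ(τ) sums the standard-normal density over the fitted probit
thresholds (the polyserial attenuation identity), σ_x is the item s.d.
from the class probabilities, and var(x_j|z) is the empirical variance of
the residual expected latent values.

The unequal information across missingness patterns makes scores
heteroskedastic; per pattern the inverse-variance weight
``w_t = 1 / (A'_{−M,t} S_{−M} A_{−M,t})`` (S the residualized
pairwise-complete sample covariance) feeds downstream WLS, and a
model-implied completeness — the squared correlation between the
pattern's score and the hypothetical zero-missingness score — gates
inclusion at r² ≥ 0.8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correlations import MixedCorrelation, ProbitFit, nearest_psd, residualize_continuous
from .efa import FactorModel
from .simulate import PhenotypeTable, CONTINUOUS

BARTLETT = "bartlett"
THOMSON_THURSTONE = "thomson_thurstone"
COMPLETENESS_THRESHOLD = 0.8


def adjust_categorical(
    model: FactorModel,
    probit_fits: dict[int, ProbitFit],
    threshold_sum: str = "per_threshold",
) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation-adjust loadings and uniquenesses of categorical items.

    ``probit_fits`` maps item index → fitted probit summary; continuous
    rows pass through unchanged. ``threshold_sum`` selects how
    Σ φ(·) is accumulated: over the K−1 fitted thresholds (default,
    consistent with the polyserial attenuation identity) or over the K
    categories' lower thresholds (``"per_category"``, double-counting
    interior thresholds; provided for comparison only).
    """
    lam = model.loadings.copy()
    psi = model.uniquenesses.copy()
    for j, fit in probit_fits.items():
        if fit.sigma_x == 0:
            raise ValueError(f"item {j} constant: sigma_x = 0")
        dens = fit.density_sum
        if threshold_sum == "per_category":
            from scipy.stats import norm

            taus = np.concatenate([fit.thresholds, fit.thresholds[-1:]])
            dens = float(np.sum(norm.pdf(taus)))
        elif threshold_sum != "per_threshold":
            raise ValueError(f"unknown threshold_sum {threshold_sum!r}")
        atten = dens / fit.sigma_x
        var_xz = fit.var_xz
        lam[j] = model.loadings[j] * np.sqrt(var_xz) * atten
        psi[j] = var_xz * (1.0 - (1.0 - model.uniquenesses[j]) * atten**2)
    return lam, psi


def pattern_coefficients(
    method: str, lam: np.ndarray, psi: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Scoring coefficients for one missingness pattern.

    Returns the (n_observed × t) coefficient matrix A on the observed
    rows. Factors with no observed loaded item (or a singular information
    matrix) get NaN columns — unscorable for this pattern.
    """
    observed = np.asarray(observed)
    L = lam[observed]
    P = psi[observed]
    if np.any(P <= 0):
        raise ValueError("uniquenesses must be positive for scoring")
    t = L.shape[1]
    scorable = np.flatnonzero((L != 0).any(axis=0))
    A = np.full((L.shape[0], t), np.nan)
    if scorable.size == 0:
        return A
    Ls = L[:, scorable]
    PiL = Ls / P[:, None]
    G = Ls.T @ PiL
    M = G if method == BARTLETT else np.eye(scorable.size) + G
    if method not in (BARTLETT, THOMSON_THURSTONE):
        raise ValueError(f"unknown scoring method {method!r}")
    try:
        sol = np.linalg.solve(M, PiL.T)
    except np.linalg.LinAlgError:
        return A
    if np.linalg.cond(M) > 1e12:
        return A
    A[:, scorable] = sol.T
    return A


def score_weights(A: np.ndarray, S_observed: np.ndarray) -> np.ndarray:
    """Inverse-variance weights ``w_t = 1/(A_t' S A_t)`` per factor."""
    quad = np.einsum("jt,jk,kt->t", A, S_observed, A)
    if np.any(quad[np.isfinite(quad)] <= 0):
        raise ValueError("non-positive score variance; repair S upstream")
    return 1.0 / quad


def reliability_and_completeness(
    lam: np.ndarray,
    psi: np.ndarray,
    observed: np.ndarray,
    method: str = BARTLETT,
    threshold: float = COMPLETENESS_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model-implied reliability, completeness and inclusion per factor.

    Reliability is the implied correlation between the pattern's score
    and the latent factor; completeness is the implied *squared*
    correlation between the pattern's score and the zero-missingness
    score. Inclusion requires completeness ≥ ``threshold``.
    """
    observed = np.asarray(observed)
    sigma = lam @ lam.T + np.diag(psi)
    A_m = pattern_coefficients(method, lam, psi, observed)
    full = np.arange(lam.shape[0])
    A_f = pattern_coefficients(method, lam, psi, full)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov_mf = lam[observed].T @ A_m  # cov(f, f̂_M) per factor pair; need diag
        var_m = np.einsum("jt,jk,kt->t", A_m, sigma[np.ix_(observed, observed)], A_m)
        reliability = np.abs(np.diag(cov_mf)) / np.sqrt(var_m)
        var_f = np.einsum("jt,jk,kt->t", A_f, sigma, A_f)
        cov_mf_full = np.einsum("jt,jk,kt->t", A_m, sigma[observed][:, full], A_f)
        completeness = cov_mf_full**2 / (var_m * var_f)
    if observed.size == 0:
        reliability = np.full(lam.shape[1], np.nan)
        completeness = np.full(lam.shape[1], np.nan)
    included = completeness >= threshold
    return reliability, completeness, included


@dataclass
class PatternEntry:
    observed: np.ndarray
    coefficients: np.ndarray
    weights: np.ndarray
    reliability: np.ndarray
    completeness: np.ndarray
    included: np.ndarray


@dataclass
class ScoringCoefficientSet:
    """Per-missingness-pattern scoring coefficients, weights and gates.

    Patterns are keyed by the frozenset of missing *loaded* items: items
    with an all-zero loading row cannot change any factor's coefficients,
    which collapses the pattern space without approximation.
    """

    method: str
    adjusted_loadings: np.ndarray
    adjusted_uniquenesses: np.ndarray
    sample_cov: np.ndarray
    item_labels: list[str]
    completeness_threshold: float = COMPLETENESS_THRESHOLD
    patterns: dict[frozenset, PatternEntry] = field(default_factory=dict)
    loaded_items: np.ndarray = None

    def __post_init__(self):
        if self.loaded_items is None:
            self.loaded_items = np.flatnonzero((self.adjusted_loadings != 0).any(axis=1))

    @property
    def t(self) -> int:
        return self.adjusted_loadings.shape[1]

    def entry(self, missing_items: np.ndarray) -> PatternEntry:
        """Pattern entry for a set of missing item indices (cached)."""
        key = frozenset(int(j) for j in np.intersect1d(missing_items, self.loaded_items))
        if key not in self.patterns:
            p = self.adjusted_loadings.shape[0]
            observed = np.setdiff1d(np.arange(p), np.fromiter(key, int, len(key)))
            A = pattern_coefficients(
                self.method, self.adjusted_loadings, self.adjusted_uniquenesses, observed
            )
            finite = (
                np.isfinite(A).all(axis=0)
                if A.shape[0]
                else np.zeros(self.t, dtype=bool)
            )
            w = np.full(self.t, np.nan)
            if finite.any():
                w[finite] = score_weights(
                    A[:, finite], self.sample_cov[np.ix_(observed, observed)]
                )
            rel, comp, inc = reliability_and_completeness(
                self.adjusted_loadings,
                self.adjusted_uniquenesses,
                observed,
                self.method,
                self.completeness_threshold,
            )
            inc = inc & finite
            self.patterns[key] = PatternEntry(observed, A, w, rel, comp, inc)
        return self.patterns[key]

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "item_labels": self.item_labels,
            "adjusted_loadings": self.adjusted_loadings.tolist(),
            "adjusted_uniquenesses": self.adjusted_uniquenesses.tolist(),
            "patterns": [
                {
                    "missing": sorted(key),
                    "observed": entry.observed.tolist(),
                    "coefficients": entry.coefficients.tolist(),
                    "weights": entry.weights.tolist(),
                    "reliability": entry.reliability.tolist(),
                    "completeness": entry.completeness.tolist(),
                }
                for key, entry in self.patterns.items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class FactorScoreMatrix:
    """Per-individual factor scores with weights, reliabilities, gates."""

    scores: np.ndarray
    weights: np.ndarray
    reliability: np.ndarray
    completeness: np.ndarray
    included: np.ndarray

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def t(self) -> int:
        return self.scores.shape[1]

    def frame(self, factor: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.scores[:, factor],
                "weight": self.weights[:, factor],
                "reliability": self.reliability[:, factor],
                "completeness": self.completeness[:, factor],
                "included": self.included[:, factor],
            }
        )

    def to_tsv(self, path) -> None:
        t = self.t
        frames = []
        for f in range(t):
            df = self.frame(f)
            df.insert(0, "factor", f)
            df.insert(0, "individual", np.arange(self.n))
            frames.append(df)
        pd.concat(frames).to_csv(path, sep="\t", index=False)


def prepare_scoring_values(
    table: PhenotypeTable, probit_fits: dict[int, ProbitFit]
) -> np.ndarray:
    """Item values on the scoring scale.

    Continuous items: covariate residuals standardized to unit variance.
    Categorical items: residual expected latent values from the probit
    fits. Missing cells stay NaN.
    """
    values = np.full_like(table.values, np.nan, dtype=float)
    cont = table.scales == CONTINUOUS
    Z = table.covariates if table.covariates.shape[1] else None
    if cont.any():
        values[:, cont] = residualize_continuous(table.values[:, cont], Z)
    for j, fit in probit_fits.items():
        values[:, j] = fit.expected_resid
    return values


def build_scoring_coefficients(
    model: FactorModel,
    scoring_values: np.ndarray,
    probit_fits: dict[int, ProbitFit] | None = None,
    method: str = BARTLETT,
    completeness_threshold: float = COMPLETENESS_THRESHOLD,
    threshold_sum: str = "per_threshold",
) -> ScoringCoefficientSet:
    """Assemble the full scoring machinery from a fitted factor model.

    ``scoring_values`` are the residualized/substituted item values (see
    :func:`prepare_scoring_values`); their pairwise-complete covariance
    becomes S of the inverse-variance weights (PSD-repaired if needed).
    """
    lam, psi = adjust_categorical(model, probit_fits or {}, threshold_sum)
    if np.any(psi <= 0):
        bad = np.flatnonzero(psi <= 0).tolist()
        raise ValueError(f"non-positive adjusted uniquenesses for items {bad}")
    df = pd.DataFrame(scoring_values)
    S = df.cov(min_periods=2).to_numpy()
    d = np.sqrt(np.diag(S))
    corr = S / np.outer(d, d)
    repaired, was = nearest_psd(np.where(np.isnan(corr), 0.0, corr))
    if was:
        S = repaired * np.outer(d, d)
    return ScoringCoefficientSet(
        method=method,
        adjusted_loadings=lam,
        adjusted_uniquenesses=psi,
        sample_cov=S,
        item_labels=list(model.item_labels),
        completeness_threshold=completeness_threshold,
    )


def score_individuals(
    scoring_values: np.ndarray, coef_set: ScoringCoefficientSet
) -> FactorScoreMatrix:
    """Score every individual with pattern-specific coefficients.

    Rows are grouped by their missingness pattern over loaded items; each
    pattern's coefficient matrix is computed once and cached on the
    coefficient set. A factor's score is missing only when every item
    loading on it is missing (or the pattern is unscorable).
    """
    X = np.asarray(scoring_values, dtype=float)
    n, p = X.shape
    t = coef_set.t
    scores = np.full((n, t), np.nan)
    weights = np.full((n, t), np.nan)
    reliability = np.full((n, t), np.nan)
    completeness = np.full((n, t), np.nan)
    included = np.zeros((n, t), dtype=bool)

    loaded = coef_set.loaded_items
    miss = np.isnan(X[:, loaded])
    # group rows sharing a missingness pattern over loaded items
    codes, inverse = np.unique(miss, axis=0, return_inverse=True)
    for g in range(codes.shape[0]):
        rows = np.flatnonzero(inverse == g)
        missing_items = loaded[codes[g]]
        entry = coef_set.entry(missing_items)
        A = entry.coefficients
        ok = np.isfinite(A).all(axis=0) if A.shape[0] else np.zeros(t, dtype=bool)
        if ok.any():
            xobs = X[np.ix_(rows, entry.observed)]
            xobs = np.where(np.isnan(xobs), 0.0, xobs)  # unloaded leftovers
            scores[np.ix_(rows, np.flatnonzero(ok))] = xobs @ A[:, ok]
        weights[rows] = entry.weights
        reliability[rows] = entry.reliability
        completeness[rows] = entry.completeness
        included[rows] = entry.included

    included &= np.isfinite(scores)
    return FactorScoreMatrix(scores, weights, reliability, completeness, included)
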