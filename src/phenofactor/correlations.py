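"""Covariate-conditional mixed-type correlation estimation.

Continuous items are residualized on the nuisance covariates and
standardized; categorical items are modelled by covariate-conditional
ordered probit. Pairwise latent correlations are then estimated with the
estimator appropriate to the pair's measurement scales — Pearson for two
continuous items, polyserial for continuous × categorical, polychoric
for two categorical — using the two-step approach (marginal thresholds
and probit coefficients first, the correlation by maximum likelihood
second, as in lavaan-style practice).

Each pairwise estimate carries its pairwise-complete sample size and an
asymptotic variance (delta method for Pearson, inverse observed
information for polyserial/polychoric) which downstream DWLS uses as
inverse weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .simulate import PhenotypeTable, CONTINUOUS

RHO_CLIP = 0.9999
_INF = 12.0  # effective ±infinity on the standard-normal scale

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = np.polynomial.legendre.leggauss(n)
    return _GL_CACHE[n]


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float, n_nodes: int = 32) -> np.ndarray:
    """P(X ≤ h, Y ≤ k) for standard bivariate normal with correlation rho.

    Vectorized over ``h``/``k`` via Gauss–Legendre quadrature of the
    single integral representation Φ₂ = Φ(h)Φ(k) + (2π)⁻¹∫₀^ρ
    exp(−(h²−2rhk+k²)/(2(1−r²)))/√(1−r²) dr.
    """
    h = np.clip(np.asarray(h, dtype=float), -_INF, _INF)
    k = np.clip(np.asarray(k, dtype=float), -_INF, _INF)
    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base
    x, w = _gauss_legendre(n_nodes)
    r = 0.5 * rho * (x + 1.0)  # nodes on [0, rho]
    wr = 0.5 * rho * w
    hh = h[..., None]
    kk = k[..., None]
    om = 1.0 - r**2
    integrand = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * om)) / np.sqrt(om)
    return base + (integrand @ wr) / (2.0 * np.pi)


class _RectProb:
    """Rectangle probabilities P(alo < X ≤ ahi, blo < Y ≤ bhi) as a
    function of the correlation, with everything rho-independent cached.

    The four inclusion–exclusion corners are flattened; corners with an
    infinite coordinate contribute only to the rho-independent base term
    (their integrand vanishes), so they are excluded from the quadrature.
    """

    def __init__(self, alo, ahi, blo, bhi, n_nodes: int = 32):
        alo, ahi, blo, bhi = np.broadcast_arrays(alo, ahi, blo, bhi)
        self.shape = alo.shape
        n = alo.size
        h = np.clip(np.stack([ahi, alo, ahi, alo]).reshape(4, n), -_INF, _INF)
        k = np.clip(np.stack([bhi, bhi, blo, blo]).reshape(4, n), -_INF, _INF)
        sign = np.array([1.0, -1.0, -1.0, 1.0])[:, None]
        self.base = np.sum(sign * ndtr(h) * ndtr(k), axis=0)
        active = (np.abs(h) < _INF) & (np.abs(k) < _INF)
        self.h = h[active][:, None]
        self.k = k[active][:, None]
        self.sign = np.broadcast_to(sign, h.shape)[active]
        self.idx = np.broadcast_to(np.arange(n), h.shape)[active]
        self.hk = self.h * self.k
        self.h2k2 = self.h**2 + self.k**2
        self.n = n
        self.x, self.w = _gauss_legendre(n_nodes)

    def __call__(self, rho: float) -> np.ndarray:
        out = self.base.copy()
        if rho != 0.0 and self.h.size:
            r = 0.5 * rho * (self.x + 1.0)
            om = 1.0 - r**2
            wr = (0.5 * rho * self.w) / (np.sqrt(om) * 2.0 * np.pi)
            integrand = np.exp((2.0 * self.hk * r - self.h2k2) / (2.0 * om))
            contrib = self.sign * (integrand @ wr)
            out += np.bincount(self.idx, weights=contrib, minlength=self.n)
        return out.reshape(self.shape)


def _rect_prob(alo, ahi, blo, bhi, rho: float) -> np.ndarray:
    """P(alo < X ≤ ahi, blo < Y ≤ bhi) elementwise."""
    return _RectProb(np.asarray(alo, float), np.asarray(ahi, float),
                     np.asarray(blo, float), np.asarray(bhi, float))(rho)


def _bounds_from_codes(codes: np.ndarray, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation latent interval (lo, hi] implied by ordinal codes."""
    edges = np.concatenate([[-_INF], tau, [_INF]])
    c = codes.astype(int)
    return edges[c], edges[c + 1]


@dataclass
class PairEstimate:
    rho: float
    var: float  # sampling variance of rho-hat
    n: int
    clipped: bool = False


def _numeric_avar(nll, rho_hat: float, h: float = 5e-4) -> float:
    """Inverse observed information by central second difference."""
    r = min(max(rho_hat, -RHO_CLIP + 2 * h), RHO_CLIP - 2 * h)
    d2 = (nll(r + h) - 2.0 * nll(r) + nll(r - h)) / h**2
    if not np.isfinite(d2) or d2 <= 0:
        return np.nan
    return 1.0 / d2


def _maximize_pair(nll, n: int, xatol: float) -> PairEstimate:
    res = minimize_scalar(nll, bounds=(-RHO_CLIP, RHO_CLIP), method="bounded",
                          options={"xatol": xatol})
    rho = float(res.x)
    clipped = abs(rho) >= RHO_CLIP - 10 * xatol
    if clipped:
        rho = float(np.sign(rho) * RHO_CLIP)
        warnings.warn("latent correlation at boundary; value clipped", stacklevel=3)
    var = _numeric_avar(nll, rho)
    return PairEstimate(rho, var, n, clipped)


def polychoric_from_counts(
    counts: np.ndarray, tau_a: np.ndarray, tau_b: np.ndarray, xatol: float = 1e-8
) -> PairEstimate:
    """Two-step polychoric correlation from a contingency table.

    ``counts`` may hold expected counts or cell probabilities; thresholds
    are taken as fixed. The correlation maximizes the multinomial
    likelihood of the bivariate-normal rectangle probabilities.
    """
    counts = np.asarray(counts, dtype=float)
    edges_a = np.concatenate([[-_INF], np.asarray(tau_a, float), [_INF]])
    edges_b = np.concatenate([[-_INF], np.asarray(tau_b, float), [_INF]])
    rect = _RectProb(
        edges_a[:-1][:, None], edges_a[1:][:, None],
        edges_b[None, :-1], edges_b[None, 1:], n_nodes=64,
    )

    def nll(rho: float) -> float:
        pr = np.clip(rect(rho), 1e-300, None)
        return -float(np.sum(counts * np.log(pr)))

    total = counts.sum()
    est = _maximize_pair(nll, int(round(total)), xatol)
    if np.isfinite(est.var):
        est.var = est.var  # already per the supplied counts mass
    return est


def estimate_polychoric(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    tau_a: np.ndarray,
    tau_b: np.ndarray,
    offsets_a: np.ndarray | None = None,
    offsets_b: np.ndarray | None = None,
    xatol: float = 2e-5,
) -> PairEstimate:
    """Polychoric correlation of two ordinal items, thresholds fixed.

    With covariate offsets (the probit linear predictors ``Zγ̂``) the
    likelihood uses per-observation threshold shifts; without them the
    computation collapses to the contingency-table fast path.
    """
    codes_a = np.asarray(codes_a, float)
    codes_b = np.asarray(codes_b, float)
    obs = ~(np.isnan(codes_a) | np.isnan(codes_b))
    ca, cb = codes_a[obs], codes_b[obs]
    n = int(obs.sum())
    if n == 0:
        raise ValueError("no pairwise-complete observations")

    no_offsets = (offsets_a is None or not np.any(offsets_a)) and (
        offsets_b is None or not np.any(offsets_b)
    )
    if no_offsets:
        ka, kb = len(tau_a) + 1, len(tau_b) + 1
        counts = np.zeros((ka, kb))
        np.add.at(counts, (ca.astype(int), cb.astype(int)), 1.0)
        return polychoric_from_counts(counts, tau_a, tau_b, xatol=min(xatol, 1e-6))

    oa = np.zeros(n) if offsets_a is None else np.asarray(offsets_a, float)[obs]
    ob = np.zeros(n) if offsets_b is None else np.asarray(offsets_b, float)[obs]
    alo, ahi = _bounds_from_codes(ca, np.asarray(tau_a, float))
    blo, bhi = _bounds_from_codes(cb, np.asarray(tau_b, float))
    rect = _RectProb(alo - oa, ahi - oa, blo - ob, bhi - ob)

    def nll(rho: float) -> float:
        pr = np.clip(rect(rho), 1e-300, None)
        return -float(np.sum(np.log(pr)))

    return _maximize_pair(nll, n, xatol)


def estimate_polyserial(
    w: np.ndarray,
    codes: np.ndarray,
    tau: np.ndarray,
    offsets: np.ndarray | None = None,
    xatol: float = 1e-6,
) -> PairEstimate:
    """Polyserial correlation of a standardized continuous item with an
    ordinal item (two-step, conditional-likelihood form).

    Given the latent correlation ρ, the ordinal item's latent residual
    conditional on the observed continuous value ``w`` is
    ``N(ρ·w, 1−ρ²)``; the likelihood multiplies the implied interval
    probabilities over observations.
    """
    w = np.asarray(w, float)
    codes = np.asarray(codes, float)
    obs = ~(np.isnan(w) | np.isnan(codes))
    ww, cc = w[obs], codes[obs]
    n = int(obs.sum())
    if n == 0:
        raise ValueError("no pairwise-complete observations")
    if np.nanstd(ww) == 0:
        raise ValueError("continuous item has zero variance")
    off = np.zeros(n) if offsets is None else np.asarray(offsets, float)[obs]
    lo, hi = _bounds_from_codes(cc, np.asarray(tau, float))
    lo, hi = lo - off, hi - off

    def nll(rho: float) -> float:
        s = np.sqrt(1.0 - rho**2)
        pr = ndtr((hi - rho * ww) / s) - ndtr((lo - rho * ww) / s)
        return -float(np.sum(np.log(np.clip(pr, 1e-300, None))))

    return _maximize_pair(nll, n, xatol)


# ---------------------------------------------------------------------------
# ordered probit per item


@dataclass
class ProbitFit:
    """Covariate-conditional ordered probit fit of one categorical item.

    ``thresholds`` follow the code-above-threshold convention: the
    observed code counts thresholds lying below the latent value
    ``Zγ + e``, ``e ~ N(0,1)``. ``expected_resid`` holds, per observed
    individual, E[e | code, Z] — the residual expected latent value that
    substitutes for the raw code in scoring and polyserial/polychoric
    estimation; ``var_xz`` is its empirical variance and ``sigma_x`` the
    item s.d. implied by the marginal class probabilities.
    """

    thresholds: np.ndarray
    coefs: np.ndarray
    sigma_x: float
    class_probs: np.ndarray
    expected_resid: np.ndarray
    offsets: np.ndarray
    var_xz: float
    codes: np.ndarray  # possibly collapsed, NaN where missing
    collapsed: list[tuple[int, int]] = field(default_factory=list)

    @property
    def density_sum(self) -> float:
        """Σ_τ φ(τ): total standard-normal density mass at the thresholds."""
        return float(np.sum(stats.norm.pdf(self.thresholds)))


def _collapse_rare(codes: np.ndarray, min_count: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Merge categories observed fewer than ``min_count`` times into an
    adjacent category (downward when possible), recoding to 0..K−1."""
    out = codes.copy()
    merges: list[tuple[int, int]] = []
    while True:
        obs = out[~np.isnan(out)].astype(int)
        levels, counts = np.unique(obs, return_counts=True)
        if len(levels) < 2:
            raise ValueError("item constant after collapsing rare categories")
        small = np.flatnonzero(counts < min_count)
        if small.size == 0:
            break
        i = small[np.argmin(counts[small])]
        target = levels[i - 1] if i > 0 else levels[i + 1]
        out[out == levels[i]] = target
        merges.append((int(levels[i]), int(target)))
    # dense recode preserving order
    levels = np.unique(out[~np.isnan(out)]).astype(int)
    remap = {lv: r for r, lv in enumerate(levels)}
    dense = out.copy()
    for lv, r in remap.items():
        dense[out == lv] = r
    return dense, merges


def fit_probit_item(
    codes: np.ndarray,
    covariates: np.ndarray | None = None,
    min_category_count: int = 5,
) -> ProbitFit:
    """Fit an ordered probit of an ordinal/binary item on covariates.

    Without covariates the thresholds are the normal quantiles of the
    cumulative class proportions; with covariates a full ordered-probit
    maximum-likelihood fit is used (statsmodels ``OrderedModel``).
    """
    codes = np.asarray(codes, dtype=float)
    obs = ~np.isnan(codes)
    if obs.sum() == 0:
        raise ValueError("item entirely missing")
    codes, merges = _collapse_rare(codes, min_category_count)
    obs_codes = codes[obs].astype(int)
    k = int(obs_codes.max()) + 1
    counts = np.bincount(obs_codes, minlength=k).astype(float)
    probs = counts / counts.sum()

    n = codes.shape[0]
    offsets = np.zeros(n)
    if covariates is None or covariates.size == 0 or covariates.shape[1] == 0:
        tau = stats.norm.ppf(np.cumsum(probs)[:-1])
        coefs = np.zeros(0)
    else:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        Z = np.asarray(covariates, dtype=float)[obs]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(obs_codes, Z, distr="probit")
            res = model.fit(method="bfgs", disp=False, maxiter=300, gtol=1e-7)
        q = Z.shape[1]
        coefs = np.asarray(res.params[:q], dtype=float)
        tau = np.asarray(model.transform_threshold_params(res.params), dtype=float)[1:-1]
        offsets = np.full(n, np.nan)
        offsets[obs] = np.asarray(covariates, dtype=float)[obs] @ coefs
        offsets = np.where(np.isnan(offsets), 0.0, offsets)

    # residual expected latent value E[e | code, Z]
    lo, hi = _bounds_from_codes(np.where(obs, codes, 0.0), tau)
    a = lo - offsets
    b = hi - offsets
    pa, pb = stats.norm.cdf(a), stats.norm.cdf(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = (stats.norm.pdf(a) - stats.norm.pdf(b)) / np.clip(pb - pa, 1e-300, None)
    expected = np.where(obs, ev, np.nan)

    codes_levels = np.arange(k)
    mean_x = float(probs @ codes_levels)
    sigma_x = float(np.sqrt(probs @ (codes_levels - mean_x) ** 2))
    if sigma_x == 0:
        raise ValueError("constant item: sigma_x is zero")
    var_xz = float(np.var(expected[obs]))

    return ProbitFit(
        thresholds=tau,
        coefs=coefs,
        sigma_x=sigma_x,
        class_probs=probs,
        expected_resid=expected,
        offsets=offsets,
        var_xz=var_xz,
        codes=codes,
        collapsed=merges,
    )


# ---------------------------------------------------------------------------
# residualization and the mixed matrix


def _check_covariate_rank(Z: np.ndarray) -> None:
    design = np.column_stack([np.ones(Z.shape[0]), Z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        for j in range(Z.shape[1]):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(j)
        raise ValueError(f"covariate matrix rank-deficient; collinear columns: {bad}")


def residualize_continuous(
    values: np.ndarray, covariates: np.ndarray | None, standardize: bool = True
) -> np.ndarray:
    """Per-item least-squares residual on covariates plus intercept.

    Each column is fit on its own observed rows; missing rows get missing
    residuals. Residuals are standardized to unit variance by default.
    """
    values = np.asarray(values, dtype=float)
    one_col = values.ndim == 1
    if one_col:
        values = values[:, None]
    n, p = values.shape
    Z = np.zeros((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if Z.shape[1]:
        _check_covariate_rank(Z)
    design = np.column_stack([np.ones(n), Z])
    out = np.full_like(values, np.nan)
    for j in range(p):
        obs = ~np.isnan(values[:, j])
        if obs.sum() < design.shape[1] + 1:
            continue
        beta, *_ = np.linalg.lstsq(design[obs], values[obs, j], rcond=None)
        resid = values[obs, j] - design[obs] @ beta
        if standardize:
            sd = resid.std(ddof=1)
            if sd == 0:
                raise ValueError(f"item column {j} constant after residualization")
            resid = resid / sd
        out[obs, j] = resid
    return out[:, 0] if one_col else out


@dataclass
class MixedCorrelation:
    """Covariate-conditional item correlation matrix with pair metadata.

    ``matrix`` is symmetric with unit diagonal; ``pair_method`` labels
    each pair pearson/polyserial/polychoric; ``pair_n`` counts
    pairwise-complete observations and ``pair_var`` holds the
    per-observation asymptotic variance ``n·avar(r̂)`` used to form DWLS
    weights. Categorical items carry their fitted probit summaries.
    """

    matrix: np.ndarray
    pair_method: np.ndarray
    pair_n: np.ndarray
    pair_var: np.ndarray
    item_labels: list[str]
    scales: np.ndarray
    probit_fits: dict[int, ProbitFit] = field(default_factory=dict)
    flagged_pairs: list[tuple[int, int]] = field(default_factory=list)
    n: int = 0

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def subset(self, keep: np.ndarray) -> "MixedCorrelation":
        keep = np.asarray(keep)
        idx = {int(j): r for r, j in enumerate(keep)}
        return MixedCorrelation(
            matrix=self.matrix[np.ix_(keep, keep)],
            pair_method=self.pair_method[np.ix_(keep, keep)],
            pair_n=self.pair_n[np.ix_(keep, keep)],
            pair_var=self.pair_var[np.ix_(keep, keep)],
            item_labels=[self.item_labels[j] for j in keep],
            scales=self.scales[keep],
            probit_fits={idx[j]: f for j, f in self.probit_fits.items() if j in idx},
            flagged_pairs=[
                (idx[a], idx[b]) for a, b in self.flagged_pairs if a in idx and b in idx
            ],
            n=self.n,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.item_labels, columns=self.item_labels).to_csv(
            path, sep="\t"
        )


def nearest_psd(matrix: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Repair a symmetric matrix by clipping eigenvalues at ``floor`` and
    rescaling back to unit diagonal. Returns (repaired, was_repaired)."""
    matrix = 0.5 * (matrix + matrix.T)
    vals, vecs = np.linalg.eigh(matrix)
    if vals.min() >= floor:
        return matrix, False
    fixed = (vecs * np.clip(vals, floor, None)) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def _pairwise_pearson(X: np.ndarray, a: int, b: int, min_n: int):
    obs = ~(np.isnan(X[:, a]) | np.isnan(X[:, b]))
    n = int(obs.sum())
    if n < max(min_n, 3):
        return np.nan, np.nan, n
    xa, xb = X[obs, a], X[obs, b]
    sa, sb = xa.std(), xb.std()
    if sa == 0 or sb == 0:
        return np.nan, np.nan, n
    r = float(np.clip(np.mean((xa - xa.mean()) * (xb - xb.mean())) / (sa * sb),
                      -RHO_CLIP, RHO_CLIP))
    return r, (1.0 - r**2) ** 2, n


def build_mixed_correlation(
    table: PhenotypeTable,
    min_pair_n: int = 100,
    min_category_count: int = 5,
    probit_fits: dict[int, ProbitFit] | None = None,
) -> MixedCorrelation:
    """Estimate the full mixed-type correlation matrix of a filtered table.

    Dispatches per item pair on measurement scales, uses
    pairwise-complete rows throughout, and records per-pair sample sizes
    and asymptotic variances. Pairs with fewer than ``min_pair_n``
    complete rows are left missing and flagged.
    """
    p = table.p
    scales = table.scales
    Z = table.covariates
    cont = scales == CONTINUOUS

    resid = np.full_like(table.values, np.nan)
    if cont.any():
        resid[:, cont] = residualize_continuous(table.values[:, cont], Z)

    if probit_fits is None:
        probit_fits = {}
        for j in np.flatnonzero(~cont):
            probit_fits[int(j)] = fit_probit_item(
                table.values[:, j], Z if Z.shape[1] else None, min_category_count
            )

    matrix = np.eye(p)
    method = np.full((p, p), "", dtype=object)
    pair_n = np.zeros((p, p), dtype=int)
    pair_var = np.zeros((p, p))
    flagged: list[tuple[int, int]] = []

    for a in range(p):
        pair_n[a, a] = int((~np.isnan(table.values[:, a])).sum())
        for b in range(a + 1, p):
            if cont[a] and cont[b]:
                r, v, n_ab = _pairwise_pearson(resid, a, b, min_pair_n)
                meth = "pearson"
            elif not cont[a] and not cont[b]:
                fa, fb = probit_fits[a], probit_fits[b]
                obs = ~(np.isnan(fa.codes) | np.isnan(fb.codes))
                n_ab = int(obs.sum())
                meth = "polychoric"
                if n_ab >= min_pair_n:
                    est = estimate_polychoric(
                        fa.codes, fb.codes, fa.thresholds, fb.thresholds,
                        fa.offsets, fb.offsets,
                    )
                    r, v = est.rho, est.var * est.n
                else:
                    r = v = np.nan
            else:
                jc, jo = (a, b) if cont[a] else (b, a)
                fo = probit_fits[jo]
                obs = ~(np.isnan(resid[:, jc]) | np.isnan(fo.codes))
                n_ab = int(obs.sum())
                meth = "polyserial"
                if n_ab >= min_pair_n:
                    est = estimate_polyserial(
                        resid[:, jc], fo.codes, fo.thresholds, fo.offsets
                    )
                    r, v = est.rho, est.var * est.n
                else:
                    r = v = np.nan
            if n_ab < min_pair_n or not np.isfinite(r):
                flagged.append((a, b))
                r = np.nan
                v = np.nan
            matrix[a, b] = matrix[b, a] = r
            method[a, b] = method[b, a] = meth
            pair_n[a, b] = pair_n[b, a] = n_ab
            pair_var[a, b] = pair_var[b, a] = v

    return MixedCorrelation(
        matrix=matrix,
        pair_method=method,
        pair_n=pair_n,
        pair_var=pair_var,
        item_labels=table.item_labels,
        scales=scales.copy(),
        probit_fits=probit_fits,
        flagged_pairs=flagged,
        n=table.n,
    )


def build_pearson_correlation(table: PhenotypeTable, min_pair_n: int = 100) -> MixedCorrelation:
    """Plain partial-Pearson correlation matrix for the EFA stage.

    All items — categorical ones coded numerically — are residualized on
    the covariates per item on observed rows, standardized, and
    correlated with pairwise deletion.
    """
    p = table.p
    Z = table.covariates if table.covariates.shape[1] else None
    resid = residualize_continuous(table.values, Z)
    matrix = np.eye(p)
    method = np.full((p, p), "pearson", dtype=object)
    pair_n = np.zeros((p, p), dtype=int)
    pair_var = np.zeros((p, p))
    flagged: list[tuple[int, int]] = []
    for a in range(p):
        pair_n[a, a] = int((~np.isnan(table.values[:, a])).sum())
        for b in range(a + 1, p):
            r, v, n_ab = _pairwise_pearson(resid, a, b, min_pair_n)
            if n_ab < min_pair_n or not np.isfinite(r):
                flagged.append((a, b))
                r = v = np.nan
            matrix[a, b] = matrix[b, a] = r
            pair_n[a, b] = pair_n[b, a] = n_ab
            pair_var[a, b] = pair_var[b, a] = v
    method[np.diag_indices(p)] = ""
    return MixedCorrelation(
        matrix=matrix,
        pair_method=method,
        pair_n=pair_n,
        pair_var=pair_var,
        item_labels=table.item_labels,
        scales=table.scales.copy(),
        flagged_pairs=flagged,
        n=table.n,
    )
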