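"""Synthetic phenome generator with known latent structure.

Emulates the data-generating process assumed by the downstream factor
model: an orthogonal-factor decomposition ``X = F Λ' + ε`` on a
standardized latent scale, mixed measurement scales produced by
probit-thresholding the latent values, linear nuisance-covariate effects,
questionnaire-block structured missingness plus sporadic item-wise
missingness, and rare extreme outliers in continuous items.

Every stage draws from its own child stream of one global seed, so a
stage is reproducible in isolation and the full generative path is
byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
ORDINAL = "ordinal"
BINARY = "binary"

# substream indices of the global seed
_STAGE_FACTORS = 0
_STAGE_COVARIATES = 1
_STAGE_NOISE = 2
_STAGE_MISSINGNESS = 3
_STAGE_OUTLIERS = 4


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for one pipeline stage of one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic phenome.

    Parameters
    ----------
    n_individuals
        Number of rows to draw.
    loadings
        ``(p, t)`` loading matrix on the standardized latent scale; each
        item's communality (row sum of squares) must stay below 1 so the
        uniqueness ``ψ = 1 − Σλ²`` is positive.
    item_scales
        Per item one of ``"continuous"``, ``"ordinal"``, ``"binary"``.
    thresholds
        For each categorical item, the K−1 strictly increasing cut points
        on the latent standard-normal scale (binary items have exactly
        one). Codes count thresholds below the latent value.
    covariate_effects
        Optional ``(p, q)`` linear coefficients of q standard-normal
        nuisance covariates. For categorical items the effect shifts the
        latent variable before thresholding (a probit threshold shift);
        for continuous items it is added on the native scale.
    continuous_loc, continuous_scale
        Native-scale location/scale of continuous items (categorical
        entries ignored); defaults 0 and 1.
    blocks
        Questionnaire blocks: lists of item indices that go missing
        jointly when a block is skipped.
    block_skip
        Per-block (or scalar) probability an individual skips the block.
    random_missing_rate
        Independent item-wise missingness applied on top of block skips.
    outlier_rate, outlier_magnitude
        Per-cell probability and s.d. multiplier for injected extreme
        values in continuous items.
    """

    n_individuals: int
    loadings: np.ndarray
    item_scales: list[str]
    thresholds: dict[int, np.ndarray] = field(default_factory=dict)
    covariate_effects: np.ndarray | None = None
    continuous_loc: np.ndarray | None = None
    continuous_scale: np.ndarray | None = None
    blocks: list[list[int]] = field(default_factory=list)
    block_skip: float | list[float] = 0.0
    random_missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be a (p, t) matrix")
        self.thresholds = {
            int(j): np.asarray(tau, dtype=float) for j, tau in self.thresholds.items()
        }
        if self.covariate_effects is not None:
            self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)

    @property
    def n_items(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariate_effects is None else self.covariate_effects.shape[1]

    @property
    def block_skip_probs(self) -> np.ndarray:
        if np.isscalar(self.block_skip):
            return np.full(len(self.blocks), float(self.block_skip))
        return np.asarray(self.block_skip, dtype=float)

    def validate(self) -> None:
        p, t = self.loadings.shape
        if len(self.item_scales) != p:
            raise ValueError("item_scales length must match loadings rows")
        communality = np.sum(self.loadings**2, axis=1)
        if np.any(communality >= 1.0):
            bad = np.flatnonzero(communality >= 1.0).tolist()
            raise ValueError(f"communality >= 1 for items {bad}; no room for uniqueness")
        for j, scale in enumerate(self.item_scales):
            if scale not in (CONTINUOUS, ORDINAL, BINARY):
                raise ValueError(f"unknown scale {scale!r} for item {j}")
            if scale == CONTINUOUS:
                if j in self.thresholds:
                    raise ValueError(f"continuous item {j} must not carry thresholds")
                continue
            tau = self.thresholds.get(j)
            if tau is None or tau.size == 0:
                raise ValueError(f"categorical item {j} needs thresholds")
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"thresholds of item {j} must be strictly increasing")
            if scale == BINARY and tau.size != 1:
                raise ValueError(f"binary item {j} must have exactly one threshold")
        if self.covariate_effects is not None and self.covariate_effects.shape[0] != p:
            raise ValueError("covariate_effects rows must match items")
        seen: set[int] = set()
        for block in self.blocks:
            for j in block:
                if not 0 <= j < p:
                    raise ValueError(f"block item {j} out of range")
                if j in seen:
                    raise ValueError(f"item {j} assigned to more than one block")
                seen.add(j)
        probs = np.concatenate(
            [self.block_skip_probs, [self.random_missing_rate, self.outlier_rate]]
        )
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def n_levels(self, j: int) -> int:
        if self.item_scales[j] == CONTINUOUS:
            return 0
        return int(self.thresholds[j].size) + 1

    def to_yaml(self, path) -> None:
        """Write the spec as a plain key-value config file.

        Arrays become nested lists; ``thresholds`` is keyed by item index.
        ``from_yaml`` restores an equivalent spec.
        """
        import yaml

        payload = {
            "n_individuals": int(self.n_individuals),
            "loadings": self.loadings.tolist(),
            "item_scales": list(self.item_scales),
            "thresholds": {int(j): tau.tolist() for j, tau in self.thresholds.items()},
            "covariate_effects": (
                None if self.covariate_effects is None else self.covariate_effects.tolist()
            ),
            "continuous_loc": (
                None if self.continuous_loc is None else np.asarray(self.continuous_loc).tolist()
            ),
            "continuous_scale": (
                None
                if self.continuous_scale is None
                else np.asarray(self.continuous_scale).tolist()
            ),
            "blocks": [list(map(int, b)) for b in self.blocks],
            "block_skip": (
                float(self.block_skip)
                if np.isscalar(self.block_skip)
                else list(map(float, self.block_skip))
            ),
            "random_missing_rate": float(self.random_missing_rate),
            "outlier_rate": float(self.outlier_rate),
            "outlier_magnitude": float(self.outlier_magnitude),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "SimulationSpec":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key in ("covariate_effects", "continuous_loc", "continuous_scale"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=float)
        payload["loadings"] = np.asarray(payload["loadings"], dtype=float)
        payload["thresholds"] = {
            int(j): np.asarray(tau, dtype=float)
            for j, tau in (payload.get("thresholds") or {}).items()
        }
        return SimulationSpec(**payload)


@dataclass
class PhenotypeTable:
    """Individuals × items phenotype matrix with metadata.

    ``values`` holds continuous items in native units and categorical
    items as ordered integer codes ``0 … K−1``; missing cells are NaN.
    ``item_meta`` is indexed by item label with columns ``scale``,
    ``n_levels`` and ``block``. ``covariates`` is the ``n × q`` nuisance
    covariate matrix Z.
    """

    values: np.ndarray
    item_meta: pd.DataFrame
    covariates: np.ndarray
    provenance: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def item_labels(self) -> list[str]:
        return list(self.item_meta.index)

    @property
    def scales(self) -> np.ndarray:
        return self.item_meta["scale"].to_numpy()

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(
            self.values.copy(),
            self.item_meta.copy(),
            self.covariates.copy(),
            list(self.provenance),
        )

    def subset_items(self, keep: np.ndarray) -> "PhenotypeTable":
        keep = np.asarray(keep)
        return PhenotypeTable(
            self.values[:, keep],
            self.item_meta.iloc[keep].copy(),
            self.covariates,
            list(self.provenance),
        )

    def subset_rows(self, keep: np.ndarray) -> "PhenotypeTable":
        keep = np.asarray(keep)
        return PhenotypeTable(
            self.values[keep],
            self.item_meta.copy(),
            self.covariates[keep],
            list(self.provenance),
        )

    def to_tsv(self, values_path, meta_path=None) -> None:
        df = pd.DataFrame(self.values, columns=self.item_labels)
        df.to_csv(values_path, sep="\t", index=False, na_rep="")
        if meta_path is not None:
            self.item_meta.to_csv(meta_path, sep="\t", index_label="item")

    @staticmethod
    def from_tsv(values_path, meta_path, covariates=None) -> "PhenotypeTable":
        df = pd.read_csv(values_path, sep="\t")
        meta = pd.read_csv(meta_path, sep="\t", index_col="item")
        cov = np.zeros((len(df), 0)) if covariates is None else np.asarray(covariates)
        return PhenotypeTable(df.to_numpy(dtype=float), meta, cov)


@dataclass
class TrueModel:
    """Generating parameters and latent draws of one synthetic phenome."""

    loadings: np.ndarray
    uniquenesses: np.ndarray
    factor_scores: np.ndarray
    latent_continuous: np.ndarray

    def implied_corr(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.uniquenesses)

    def to_json(self, path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _item_labels(p: int) -> list[str]:
    return [f"item{j:03d}" for j in range(p)]


def _build_meta(spec: SimulationSpec) -> pd.DataFrame:
    block_of = np.full(spec.n_items, -1)
    for b, items in enumerate(spec.blocks):
        for j in items:
            block_of[j] = b
    return pd.DataFrame(
        {
            "scale": spec.item_scales,
            "n_levels": [spec.n_levels(j) for j in range(spec.n_items)],
            "block": block_of,
        },
        index=_item_labels(spec.n_items),
    )


def simulate_phenome(spec: SimulationSpec) -> tuple[PhenotypeTable, TrueModel]:
    """Draw a complete phenotype table and its generating truth.

    The latent continuous value of item j is ``FΛ'_j + ε_j`` with
    ``ε_j ~ N(0, ψ_j)`` and ``ψ_j = 1 − Σ_t λ_jt²``, i.e. unit latent
    variance. Continuous items are mapped to their native scale and
    covariate effects added linearly; categorical items are produced by
    thresholding ``latent + Zβ`` (covariates acting as threshold shifts
    on the probit scale). No missingness is applied here.
    """
    spec.validate()
    n, p, t = spec.n_individuals, spec.n_items, spec.n_factors
    psi = 1.0 - np.sum(spec.loadings**2, axis=1)

    F = _stage_rng(spec.seed, _STAGE_FACTORS).standard_normal((n, t))
    q = spec.n_covariates
    Z = _stage_rng(spec.seed, _STAGE_COVARIATES).standard_normal((n, q))
    eps = _stage_rng(spec.seed, _STAGE_NOISE).standard_normal((n, p)) * np.sqrt(psi)

    latent = F @ spec.loadings.T + eps
    shift = Z @ spec.covariate_effects.T if q else np.zeros((n, p))

    loc = np.zeros(p) if spec.continuous_loc is None else np.asarray(spec.continuous_loc, float)
    sca = np.ones(p) if spec.continuous_scale is None else np.asarray(spec.continuous_scale, float)

    values = np.empty((n, p))
    for j, scale in enumerate(spec.item_scales):
        if scale == CONTINUOUS:
            values[:, j] = loc[j] + sca[j] * latent[:, j] + shift[:, j]
        else:
            tau = spec.thresholds[j]
            values[:, j] = np.searchsorted(tau, latent[:, j] + shift[:, j], side="left")

    table = PhenotypeTable(values, _build_meta(spec), Z, [f"simulated(seed={spec.seed})"])
    truth = TrueModel(spec.loadings.copy(), psi, F, latent)
    return table, truth


def inject_missingness(table: PhenotypeTable, spec: SimulationSpec) -> PhenotypeTable:
    """Apply block-skip and item-wise random missingness.

    For each individual and questionnaire block, with the block's skip
    probability all of the block's items are set missing jointly; an
    independent per-cell Bernoulli missingness is applied on top.
    """
    spec.validate()
    rng = _stage_rng(spec.seed, _STAGE_MISSINGNESS)
    out = table.copy()
    n = out.n
    for items, prob in zip(spec.blocks, spec.block_skip_probs):
        if prob <= 0 or not items:
            continue
        skip = rng.random(n) < prob
        out.values[np.ix_(skip, np.asarray(items))] = np.nan
    if spec.random_missing_rate > 0:
        cells = rng.random(out.values.shape) < spec.random_missing_rate
        out.values[cells] = np.nan
    out.provenance.append(
        f"missingness(blocks={len(spec.blocks)}, skip={spec.block_skip}, "
        f"item_rate={spec.random_missing_rate})"
    )
    return out


def inject_outliers(table: PhenotypeTable, spec: SimulationSpec) -> PhenotypeTable:
    """Replace random continuous cells by mean ± magnitude × s.d. extremes."""
    spec.validate()
    rng = _stage_rng(spec.seed, _STAGE_OUTLIERS)
    out = table.copy()
    n_injected = 0
    if spec.outlier_rate > 0:
        cont = np.flatnonzero(out.scales == CONTINUOUS)
        if cont.size == 0:
            raise ValueError("outlier injection requested but no continuous items")
        for j in cont:
            col = out.values[:, j]
            obs = ~np.isnan(col)
            hit = (rng.random(out.n) < spec.outlier_rate) & obs
            if not hit.any():
                continue
            mu, sd = np.nanmean(col), np.nanstd(col)
            signs = np.where(rng.random(int(hit.sum())) < 0.5, -1.0, 1.0)
            out.values[hit, j] = mu + signs * spec.outlier_magnitude * sd
            n_injected += int(hit.sum())
    out.provenance.append(
        f"outliers(rate={spec.outlier_rate}, magnitude={spec.outlier_magnitude}, "
        f"n_injected={n_injected})"
    )
    return out


def default_spec(
    n_individuals: int = 20_000,
    seed: int = 20240704,
    outlier_rate: float = 5e-5,
) -> SimulationSpec:
    """The repository's reference simulation: 5 factors, 40 mixed items.

    24 continuous, 10 four-level ordinal and 6 binary items, each loading
    a single factor (round-robin assignment, varying magnitudes with a
    sprinkling of negative signs), two nuisance covariates, four
    six-item questionnaire blocks with skip probability 0.2 over the
    last 24 items, 1.5% sporadic item-wise missingness, and a trickle of
    25-s.d. outliers in continuous items. Overall missingness lands near
    13%, in the ballpark of a real biobank core data group.
    """
    p, t, q = 40, 5, 2
    magnitudes = [0.80, 0.65, 0.50, 0.75, 0.60, 0.45, 0.70, 0.55]
    loadings = np.zeros((p, t))
    for j in range(p):
        lam = magnitudes[j % len(magnitudes)]
        if j % 7 == 3:
            lam = -lam
        loadings[j, j % t] = lam

    scales = [CONTINUOUS] * 24 + [ORDINAL] * 10 + [BINARY] * 6
    thresholds: dict[int, np.ndarray] = {}
    for k, j in enumerate(range(24, 34)):
        centre = -0.4 + 0.15 * k
        thresholds[j] = np.array([centre - 0.8, centre, centre + 0.9])
    for k, j in enumerate(range(34, 40)):
        thresholds[j] = np.array([-0.5 + 0.25 * k])

    effects = np.zeros((p, q))
    effects[::2, 0] = 0.30
    effects[::3, 1] = -0.20
    # native-scale continuous effects follow the item's own scale
    loc = np.where(np.arange(p) < 24, 0.5 * np.arange(p), 0.0)
    sca = np.where(np.arange(p) < 24, 1.0 + 0.05 * np.arange(p), 1.0)
    effects[:24] *= sca[:24, None]

    blocks = [list(range(16 + 6 * b, 22 + 6 * b)) for b in range(4)]

    return SimulationSpec(
        n_individuals=n_individuals,
        loadings=loadings,
        item_scales=scales,
        thresholds=thresholds,
        covariate_effects=effects,
        continuous_loc=loc,
        continuous_scale=sca,
        blocks=blocks,
        block_skip=0.2,
        random_missing_rate=0.015,
        outlier_rate=outlier_rate,
        outlier_magnitude=25.0,
        seed=seed,
    )


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of ``spec`` with a different global seed."""
    return replace(spec, seed=seed)
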