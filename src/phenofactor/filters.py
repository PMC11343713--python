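"""Item and individual QC filters applied before correlation estimation.

The filter chain removes items with high missingness, binary items with
insufficient prevalence or case counts, individuals with extreme
continuous outliers, and then iteratively prunes collinear items by
pairwise correlation and squared multiple correlation (SMC). Every
decision is recorded in a :class:`FilterReport` and the chain is
deterministic: pairs are scanned in descending |r|, and the member with
the higher missingness is removed (ties broken by the higher column
index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PhenotypeTable, CONTINUOUS, BINARY
from .correlations import residualize_continuous, nearest_psd

REASONS = (
    "high_missingness",
    "low_prevalence",
    "low_case_count",
    "pairwise_collinear",
    "smc_collinear",
    "outlier_individuals_removed",
)


@dataclass
class FilterReport:
    """Per-item dispositions plus the thresholds that produced them."""

    items: pd.DataFrame  # index item, columns disposition/reason/detail
    thresholds: dict
    n_individuals_removed: int = 0
    outlier_individuals: list[int] = field(default_factory=list)

    @property
    def kept(self) -> list[str]:
        return list(self.items.index[self.items["disposition"] == "kept"])

    @property
    def removed(self) -> pd.DataFrame:
        return self.items[self.items["disposition"] == "removed"]

    def to_tsv(self, path) -> None:
        self.items.to_csv(path, sep="\t", index_label="item")

    def to_json(self, path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "n_individuals_removed": self.n_individuals_removed,
            "items": {
                item: {"disposition": row["disposition"], "reason": row["reason"]}
                for item, row in self.items.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlation of each item on all others."""
    repaired, _ = nearest_psd(R, floor=1e-6)
    inv = np.linalg.inv(repaired)
    return 1.0 - 1.0 / np.diag(inv)


def _pairwise_corr_numeric(table: PhenotypeTable) -> np.ndarray:
    Z = table.covariates if table.covariates.shape[1] else None
    resid = residualize_continuous(table.values, Z)
    return pd.DataFrame(resid).corr(min_periods=2).to_numpy()


def apply_item_filters(
    table: PhenotypeTable,
    max_missingness: float = 0.4,
    min_prevalence: float = 0.01,
    min_cases: int = 100,
    collinearity_r: float = 0.95,
    smc_max: float = 0.98,
    outlier_sd: float = 20.0,
) -> tuple[PhenotypeTable, FilterReport]:
    """Apply the QC filter chain; returns the filtered table and report.

    Steps, in order: (1) drop items whose missingness exceeds
    ``max_missingness``; (2) drop binary items whose minority-class
    prevalence is below ``min_prevalence`` or minority count below
    ``min_cases``; (3) remove individuals with any continuous value more
    than ``outlier_sd`` standard deviations from the item mean; (4)
    iteratively break pairs with |r| > ``collinearity_r``; (5)
    iteratively drop items with SMC > ``smc_max``.
    """
    labels = table.item_labels
    disposition = {lab: ("kept", "", "") for lab in labels}
    n = table.n

    def remove(lab: str, reason: str, detail: str = "") -> None:
        disposition[lab] = ("removed", reason, detail)

    # 1) missingness cap
    miss_rate = table.missing_mask.mean(axis=0)
    for j, lab in enumerate(labels):
        if miss_rate[j] > max_missingness:
            remove(lab, "high_missingness", f"missingness={miss_rate[j]:.3f}")

    # 2) prevalence / case count for binary items
    for j, lab in enumerate(labels):
        if disposition[lab][0] == "removed" or table.scales[j] != BINARY:
            continue
        col = table.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            remove(lab, "high_missingness", "entirely missing")
            continue
        cases = int(min((obs == 0).sum(), (obs == 1).sum()))
        prevalence = cases / obs.size
        if cases < min_cases:
            remove(lab, "low_case_count", f"cases={cases}")
        elif prevalence < min_prevalence:
            remove(lab, "low_prevalence", f"prevalence={prevalence:.4f}")

    keep_idx = [j for j, lab in enumerate(labels) if disposition[lab][0] == "kept"]
    if not keep_idx:
        report = _finish_report(disposition, labels, locals())
        raise ValueError(f"no items survive QC filters; report: {report.items}")
    work = table.subset_items(np.asarray(keep_idx))

    # 3) continuous outlier individuals
    bad_rows = np.zeros(work.n, dtype=bool)
    for j in np.flatnonzero(work.scales == CONTINUOUS):
        col = work.values[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            continue
        mu, sd = col[obs].mean(), col[obs].std()
        if sd == 0:
            continue
        bad_rows |= obs & (np.abs(col - mu) > outlier_sd * sd)
    outlier_rows = np.flatnonzero(bad_rows).tolist()
    if outlier_rows:
        work = work.subset_rows(~bad_rows)
        work.provenance.append(
            f"removed {len(outlier_rows)} individuals with >{outlier_sd} s.d. "
            "continuous outliers"
        )

    # 4) pairwise collinearity, descending |r|
    while True:
        R = _pairwise_corr_numeric(work)
        np.fill_diagonal(R, 0.0)
        absR = np.abs(np.where(np.isnan(R), 0.0, R))
        if absR.max() <= collinearity_r:
            break
        a, b = np.unravel_index(np.argmax(absR), absR.shape)
        miss = work.missing_mask.mean(axis=0)
        # remove the member with higher missingness; ties -> higher index
        drop = (
            max(a, b)
            if np.isclose(miss[a], miss[b])
            else (a if miss[a] > miss[b] else b)
        )
        lab = work.item_labels[drop]
        remove(lab, "pairwise_collinear", f"|r|={absR[a, b]:.4f} with "
               f"{work.item_labels[a + b - drop]}")
        keep = np.ones(work.p, dtype=bool)
        keep[drop] = False
        work = work.subset_items(np.flatnonzero(keep))

    # 5) SMC collinearity
    while work.p > 2:
        R = _pairwise_corr_numeric(work)
        smc = _smc(np.where(np.isnan(R), 0.0, R))
        worst = int(np.argmax(smc))
        if smc[worst] <= smc_max:
            break
        lab = work.item_labels[worst]
        remove(lab, "smc_collinear", f"smc={smc[worst]:.4f}")
        keep = np.ones(work.p, dtype=bool)
        keep[worst] = False
        work = work.subset_items(np.flatnonzero(keep))

    thresholds = {
        "max_missingness": max_missingness,
        "min_prevalence": min_prevalence,
        "min_cases": min_cases,
        "collinearity_r": collinearity_r,
        "smc_max": smc_max,
        "outlier_sd": outlier_sd,
    }
    report = FilterReport(
        items=pd.DataFrame(
            [disposition[lab] for lab in labels],
            index=pd.Index(labels, name="item"),
            columns=["disposition", "reason", "detail"],
        ),
        thresholds=thresholds,
        n_individuals_removed=len(outlier_rows),
        outlier_individuals=outlier_rows,
    )
    if work.p == 0:
        raise ValueError(f"no items survive QC filters; report: {report.items}")
    return work, report


def _finish_report(disposition, labels, ctx) -> FilterReport:
    return FilterReport(
        items=pd.DataFrame(
            [disposition[lab] for lab in labels],
            index=pd.Index(labels, name="item"),
            columns=["disposition", "reason", "detail"],
        ),
        thresholds={},
    )
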