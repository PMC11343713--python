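"""Missingness-aware factor scoring with categorical adjustments.

Builds Bartlett (dependent-variable) and Thomson–Thurstone
(independent-variable) scoring coefficients from a fitted model, scores
every individual with coefficients optimized for their personal
missingness pattern, and checks the model-implied reliabilities against
the known factor draws.
"""

import numpy as np

from phenofactor import (
    build_mixed_correlation,
    default_spec,
    dwls_fit,
    fit_probit_item,
    inject_missingness,
    simulate_phenome,
)
from phenofactor.scoring import (
    BARTLETT,
    THOMSON_THURSTONE,
    build_scoring_coefficients,
    prepare_scoring_values,
    score_individuals,
)

spec = default_spec(n_individuals=8_000, seed=4)
table, truth = simulate_phenome(spec)
table = inject_missingness(table, spec)

# fit the (true-pattern) model by DWLS, then score
mixed = build_mixed_correlation(table)
cfa = dwls_fit(mixed, truth.loadings != 0, n=table.n,
               start=truth.loadings)

Z = table.covariates
probit_fits = {
    int(j): fit_probit_item(table.values[:, j], Z)
    for j in np.flatnonzero(table.scales != "continuous")
}
values = prepare_scoring_values(table, probit_fits)

for method in (BARTLETT, THOMSON_THURSTONE):
    coef = build_scoring_coefficients(cfa, values, probit_fits, method=method)
    sc = score_individuals(values, coef)
    obs = np.isfinite(sc.scores[:, 0])
    emp = np.corrcoef(sc.scores[obs, 0], truth.factor_scores[obs, 0])[0, 1]
    print(f"{method:18s} factor 0: {len(coef.patterns)} missingness patterns, "
          f"predicted reliability {np.nanmean(sc.reliability[:, 0]):.3f}, "
          f"empirical corr with truth {emp:.3f}, "
          f"included {sc.included[:, 0].mean():.1%}")

coef = build_scoring_coefficients(cfa, values, probit_fits, method=BARTLETT)
sc = score_individuals(values, coef)
w = sc.weights[:, 0]
print(f"inverse-variance weights, factor 0: {np.unique(np.round(w, 3)).size} "
      f"distinct values, range [{np.nanmin(w):.3f}, {np.nanmax(w):.3f}]")
# Individuals missing more informative items get lower weights; the
# completeness gate (r^2 >= 0.8 with the zero-missingness score) marks
# who is comparable enough to enter downstream regressions.
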