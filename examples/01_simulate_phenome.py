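"""Generate a synthetic phenome with known latent structure.

Draws the reference simulation — 5 orthogonal factors measured by 40
items of mixed scale (24 continuous, 10 four-level ordinal, 6 binary),
two nuisance covariates, questionnaire-block missingness and a trickle
of extreme outliers — and summarizes what a real cohort table would
look like.
"""

import numpy as np

from phenofactor import default_spec, inject_missingness, inject_outliers, simulate_phenome

spec = default_spec(n_individuals=10_000, seed=1)
table, truth = simulate_phenome(spec)
table = inject_outliers(inject_missingness(table, spec), spec)

print(f"individuals x items: {table.n} x {table.p}")
print(f"scales: {dict(zip(*np.unique(table.scales, return_counts=True)))}")
print(f"overall missingness: {table.missing_mask.mean():.1%}")
per_item = table.missing_mask.mean(axis=0)
print(f"item missingness: min {per_item.min():.1%}, max {per_item.max():.1%}")

binary = np.flatnonzero(table.scales == "binary")
prev = [np.nanmean(table.values[:, j]) for j in binary]
print("binary prevalences:", np.round(prev, 3))

# ground truth available for every downstream validation
print("true communalities (first 5 items):",
      np.round(np.sum(truth.loadings**2, axis=1)[:5], 3))
print("provenance:", *table.provenance, sep="\n  ")
# The table mimics a biobank core data group: block-skipping individuals
# lose whole questionnaires at once, on top of sporadic item missingness.
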