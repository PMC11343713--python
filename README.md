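# phenofactor

Distilling high-dimensional, mixed-type phenotype tables into a small
number of latent factors — and scoring, weighting and regressing those
factors correctly in the presence of structured missingness.

## Who this is for

Biobank-scale cohorts measure thousands of phenotypic items per person:
continuous biomarkers and anthropometrics, ordinal questionnaire
responses, binary diagnoses. The items are measured on different scales,
arrive in questionnaire blocks that whole subsets of participants skip,
and are contaminated by occasional extreme values. `phenofactor`
implements a complete, tested factor-analytic pipeline for such tables,
aimed at epidemiologists and statistical geneticists who want per-person
latent "phenome scores" they can safely feed into downstream regressions
(including GWAS-style analyses where the score is the outcome).

## The model

Observed items are treated as noisy measures of `t` orthogonal latent
factors on a standardized latent scale:

    X = F Λ' + ε,     Σ = Λ Λ' + Ψ

with `Λ` the p×t loading matrix, `Ψ = E[ε'ε]` diagonal (item
uniquenesses), and `Cov(F) = I`. Categorical items measure their latent
variable through probit thresholds; nuisance covariates `Z` (age, sex,
ancestry PCs, …) are residualized out of continuous items and enter the
categorical items as threshold shifts. The pipeline stages are:

1. **QC** — missingness, prevalence and case-count filters; removal of
   individuals with >20 s.d. continuous outliers; iterative pruning of
   collinear items (pairwise |r| > 0.95, SMC > 0.98).
2. **Mixed correlations** — covariate-conditional Pearson / polyserial /
   polychoric estimation per item pair (two-step maximum likelihood,
   pairwise-complete rows), with per-pair sample sizes and asymptotic
   variances.
3. **EFA** — scree/parallel/Kaiser factor-count diagnostics, MINRES
   extraction, varimax rotation, |λ| > 0.1 sparsification.
4. **CFA** — diagonally weighted least squares on the mixed matrix with
   uniquenesses tied to the unit diagonal, iterative Heywood pruning,
   RMSEA/SRMR/CFI/TLI fit indices, and fixed-loading holdout evaluation.
5. **Scoring** — Bartlett (`A_B = Ψ⁻¹Λ(Λ'Ψ⁻¹Λ)⁻¹`, conditionally
   unbiased; for scores used as outcomes) and Thomson–Thurstone
   (`A_TT = Ψ⁻¹Λ(I+Λ'Ψ⁻¹Λ)⁻¹`, minimum-MSE; for scores used as
   predictors) coefficients, recomputed per missingness pattern on each
   individual's observed items; attenuation adjustments for categorical
   items; per-pattern inverse-variance weights `w = 1/(A'SA)`,
   model-implied reliabilities, and an r² ≥ 0.8 completeness gate.
6. **Association** — WLS with the scoring weights when a score is the
   outcome; Huber–White (HC0) linear/logistic regression when it is a
   predictor; incremental R² / Nagelkerke pseudo-R² with bootstrap CIs.
7. **Validation** — a synthetic-data generator with known ground truth
   plus a recovery harness (Hungarian factor alignment, congruence,
   loading error, reliability calibration, FA-vs-PCA comparison).

Individual-level biobank data are access-restricted, so the package
validates every stage end-to-end on synthetic phenomes whose generating
loadings, thresholds, covariate effects and missingness design are known.

## Worked example

```python
from phenofactor import default_spec, run_pipeline

result = run_pipeline(default_spec())   # 5 factors, 40 mixed items, n = 20,000
print(result.recovery.congruences.min())        # 0.9999
print(result.recovery.mean_abs_loading_error)   # 0.0011
print(result.fit_train.rmsea, result.fit_holdout.rmsea)  # 0.0040  0.0105
print(result.recovery.max_calibration_error)    # 0.0093
```

On the reference simulation the CFA recovers every generating factor
with Tucker congruence above 0.999 and a mean absolute loading error of
about 0.001; the model fits the holdout split nearly as well as the
training split (RMSEA 0.010 vs 0.004, both "excellent" by the usual
benchmarks); and the model-implied score reliabilities match the
empirical correlation between estimated scores and the true latent
factors to better than 0.01 within every common missingness pattern.

The `examples/` directory holds one short narrative script per
capability (simulation, mixed correlations, EFA→CFA, scoring,
association); each prints the numbers it computes and says what they
mean. For instance `examples/05_association.py` regresses Bartlett
scores on a known exposure:

```
WLS:  beta = 0.1495 (true 0.15), SE = 0.0109, p = 1.38e-42, n = 10000
HC0 logistic: OR = 1.406 per score unit, p = 5.73e-36
delta Nagelkerke R2 = 0.0448, 95% CI [0.0252, 0.1636]
```

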