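# Methods

This note records the statistical model behind `phenofactor`, the
estimators and defaults each stage uses, what the synthetic-data
generator does and does not emulate, and the numerical and design
choices made where several defensible options existed.

## Model and assumptions

Observed items `X` (n individuals × p items) are modelled as
`X = F Λ' + ε` on a standardized latent scale: each item's latent
variable has unit variance, `Cov(F) = I` (orthogonal factors with unit
variance), and `Ψ = E[ε'ε]` is diagonal, giving the covariance
decomposition `Σ = ΛΛ' + Ψ` with `ψ_j = 1 − Σ_t λ_jt²`. Orthogonality is
an identification choice, not a claim about nature: each factor captures
covariance net of the others, and factors should be read that way.

Continuous items relate to their latent variable by a linear map
(location/scale); ordinal and binary items by probit thresholds — the
observed code counts thresholds below the latent value. Nuisance
covariates `Z` act linearly: they are residualized out of continuous
items (per item, on that item's observed rows, least squares with
intercept, residuals standardized to unit variance) and shift the
latent variable of categorical items before thresholding, which is
exactly an ordered-probit regression of the code on `Z`.

## Item QC

Filters run in a fixed order: (1) items with missingness above 0.4 are
dropped; (2) binary items need a minority-class count of at least 100
and minority prevalence of at least 1% (the case-count rule is checked
first, so a 40-case item is reported as `low_case_count`);
(3) individuals with any continuous value more than 20 s.d. from the
item mean are removed; (4) pairs with |r| > 0.95 are broken by scanning
in descending |r| and removing the member with higher missingness (ties:
higher column index), recomputing after each removal; (5) items with
squared multiple correlation > 0.98 against the remaining items are
removed one at a time, worst first. Every decision and its rule is
recorded in the `FilterReport`; the chain is deterministic and
idempotent.

## Mixed correlation estimation

Correlations are estimated per pair by the estimator the measurement
scales call for, on pairwise-complete rows:

- **Pearson** (continuous × continuous) on the standardized covariate
  residuals — a partial correlation. Asymptotic variance by the delta
  method, `(1 − r²)²/n`.
- **Polychoric** (categorical × categorical) and **polyserial**
  (continuous × categorical) by the two-step method: thresholds and
  covariate coefficients are fixed at the per-item ordered-probit
  estimates (statsmodels `OrderedModel`; closed-form normal quantiles
  when there are no covariates), then the latent correlation maximizes
  the bivariate-normal likelihood by bounded scalar optimization.
  Covariates enter as per-observation threshold shifts (`Zγ̂`), so the
  estimate is covariate-conditional rather than marginal. Asymptotic
  variances come from the inverse observed information (numerical second
  derivative at the optimum).

Bivariate-normal rectangle probabilities use the single-integral
representation of Φ₂ with Gauss–Legendre quadrature (32 nodes per-pair,
64 on contingency tables; corners with an infinite coordinate are
handled analytically). This reproduces the tetrachoric identity
`p₁₁ = 1/4 + arcsin(ρ)/(2π)` to ~1e−8.

Estimates are clipped to |ρ| ≤ 0.9999 with a warning at the boundary;
categories observed fewer than 5 times are collapsed into an adjacent
category before probit fitting; pairs with fewer than 100 complete rows
are left missing and flagged. Non-positive-definite matrices are
repaired by eigenvalue clipping at 1e−6 followed by rescaling to unit
diagonal, and every repair is visible to the caller (the returned flag).

The EFA stage deliberately uses a cruder but cheaper input, mirroring
standard practice at scale: a plain partial-Pearson matrix with
categorical items coded numerically. Per-item residualization happens on
each item's own observed rows; pairwise deletion then intersects rows
per pair. The categorical attenuation this induces shrinks EFA loadings
toward zero but rarely changes which loadings clear the sparsification
cutoff; the CFA then re-estimates magnitudes on the proper mixed matrix.

## EFA

Factor-count diagnostics report the scree (exact eigenvalues), the
Kaiser count (> 1), and parallel analysis (count of leading eigenvalues
exceeding the 95th percentile of null eigenvalues at the same n, p; null
by normal simulation by default, column permutation optionally). The
number of factors is a user decision informed by these diagnostics — the
package does not auto-select.

MINRES minimizes the off-diagonal residual sum of squares of `R − ΛΛ'`.
Given Ψ, the optimal rank-t Λ is the truncated eigendecomposition of
`R − Ψ`, so the objective is optimized over Ψ alone (equal to the sum of
squared trailing eigenvalues) with the analytic gradient
`−2·diag(R − Ψ − ΛΛ')`, by L-BFGS-B started at `1 − SMC` with
uniquenesses bounded in [1e−4, 1]. Items whose uniqueness lands on the
floor are flagged as Heywood cases rather than silently floored.

Varimax rotation is delegated to statsmodels' factor-rotation routines,
wrapped with Kaiser row normalization (the common default; switchable),
a deterministic sign convention (largest-magnitude loading per factor
positive) and reordering by variance explained. The returned transform
is orthonormal and includes the sign/permutation, so
`Λ_out = Λ_in R` exactly and communalities are invariant.

Sparsification keeps loadings with |λ| strictly greater than the cutoff
(default 0.1 — a loading of exactly 0.1 is excluded); items with no
surviving loading are dropped and logged, and factors left with fewer
than 3 items trigger an identifiability warning.

## CFA by DWLS

With the pattern fixed, the free loadings minimize
`Σ_{a<b} w_ab (s_ab − (ΛΛ')_ab)²` where `w_ab` is the inverse of the
pair's per-observation asymptotic variance (see above). Uniquenesses are
not free parameters: `ψ_j = 1 − Σ_t λ_jt²` enforces the unit diagonal
exactly and halves the parameter count. Optimization is L-BFGS-B with
the analytic gradient, started from the (sparsified) EFA loadings;
convergence tolerance 1e−8 on the discrepancy, at most 500 iterations.

A negative derived uniqueness raises a Heywood error carrying the
offending items; `prune_heywood` removes the most negative offender,
refits, and drops factors that fall below 2 free items, logging every
action. Fit indices use the uncorrected discrepancy-based chi-square
`χ² = n·F_min` (no scale-shifted/"WLSMV"-style correction — the scaled
statistics are themselves not fully robust for categorical data, and the
uncorrected versions are labelled as such), with
`RMSEA = √(max(χ²−df,0)/(df(n−1)))`, SRMR the r.m.s. off-diagonal
residual, and CFI/TLI against the zero-correlation baseline. Holdout
evaluation recomputes the indices against a correlation matrix estimated
from disjoint individuals with no re-estimation of any parameter.

## Factor scoring

Scores are weighted sums of observed items, `f̂_it = Σ_j a_jt x_ij`.
Bartlett coefficients `A_B = Ψ⁻¹Λ(Λ'Ψ⁻¹Λ)⁻¹` are conditionally unbiased
(`A'Λ = I`) and are used when the score is a regression outcome;
Thomson–Thurstone coefficients `A_TT = Ψ⁻¹Λ(I + Λ'Ψ⁻¹Λ)⁻¹` minimize
mean squared error and are used when the score is a predictor.

**Categorical items.** The raw code is replaced by its residual expected
latent value — `E[latent | code, Z]` from the probit fit minus the
covariate prediction, i.e. a truncated-normal mean. Because the observed
categorical variable covaries with the factor more weakly than the
latent variable the CFA loadings refer to, loadings and uniquenesses of
categorical rows are rescaled before scoring:

    λ*_jt = λ̂_jt √var(x_j|z) · (Σ_τ φ(τ̂)) / σ_x
    ψ*_jj = var(x_j|z) (1 − (1 − ψ_jj)(Σ_τ φ(τ̂))²/σ_x²)

where the density sum runs over the K−1 fitted thresholds, `σ_x` is the
item s.d. implied by the marginal class probabilities, and `var(x_j|z)`
is the empirical variance of the residual expected latent values,
recomputed per dataset. Summing the normal density over thresholds
(rather than once per category) follows the polyserial attenuation
identity — the observed–latent correlation of a thresholded variable is
`ρ·Σφ(τ)/σ_x` — and makes the adjusted loading exactly the regression
coefficient of the substituted value on the factor; a per-category
variant is available behind a flag for comparison but double-counts
interior thresholds.

**Missingness.** For each pattern of missing items M the coefficients
are recomputed on the observed subset (`A_{·,−M}` from the same
formulas on the surviving rows of Λ*, Ψ*). Patterns are keyed by the set
of missing items that have any non-zero loading row — items loading
nowhere cannot enter any coefficient — which collapses the pattern space
without approximation while staying exact under cross-loadings.

Because different patterns carry different information, scores are
heteroskedastic by construction. Each (individual, factor) gets an
inverse-variance weight `w = 1/(A'_{−M} S_{−M} A_{−M})` with S the
pairwise-complete sample covariance of the residualized/substituted
item values (PSD-repaired if needed; the sample rather than the
model-implied covariance is used so that model misfit inflates rather
than hides the variance). The model-implied reliability
(corr(f̂, f) from Σ* = Λ*Λ*' + Ψ*) and completeness (squared corr
between the pattern's score and the hypothetical zero-missingness
score) are attached per pattern; individuals enter downstream
factor-score regressions only when completeness ≥ 0.8 (configurable).

## Downstream association

Scores as outcome: WLS with the scoring weights, covariates always in
the design, p values from the normal approximation (appropriate at the
intended sample sizes; the t/normal difference is negligible there).
Scores as predictor: OLS or binomial GLM with Huber–White HC0 sandwich
covariance; perfect separation is flagged with no estimate rather than
returning a divergent one. Incremental variance explained is ΔR² for
linear outcomes and Δ Nagelkerke pseudo-R² for binary ones, with an
optional percentile bootstrap CI. A Bonferroni helper is provided for
families of outcomes but is applied only on request.

## Synthetic data and what passing tests show

The generator draws factors and residuals independently normal (factors
orthogonal in expectation, not sample-orthogonalized, matching
`Cov(F) = I`), produces categorical items by thresholding
`latent + Zβ` (so the probit-conditional model used in scoring is
exactly correct on synthetic data), applies questionnaire-block
missingness (per individual and block, the whole block goes missing
with the skip probability) plus independent item-wise missingness, and
injects rare `mean ± k·s.d.` outliers into continuous cells. One global
seed expands into per-stage substreams so each stage is reproducible in
isolation.

The reference simulation used by the tests and the acceptance script
has 5 factors and 40 items (24 continuous, 10 four-level ordinal, 6
binary with prevalences from ~18% to ~70%), each item loading a single
factor with magnitudes 0.45–0.8 and occasional negative signs, two
standard-normal covariates with effects on alternating items, four
six-item blocks with skip probability 0.2 over the last 24 items, 1.5%
sporadic missingness (overall missingness ≈ 13%, in the range of a real
core data group), a 5e−5 rate of 25-s.d. outliers, and n = 20,000 with
an 80:20 train/holdout split. These sizes keep a full pipeline run
under a minute on one CPU while leaving sampling error well below the
recovery tolerances.

Missingness here is completely at random given the block design. Real
questionnaire skipping is not: it correlates with the phenotypes
themselves, and the generator does not emulate informative missingness,
longitudinal structure, or non-normal latent distributions. Passing
recovery and calibration tests therefore demonstrates correctness of
the estimators and scoring algebra under the stated model, not
robustness to MNAR mechanisms or latent non-normality.

Reliability calibration compares the model-implied reliability with the
empirical corr(f̂, F_true) within groups of individuals sharing a
block-level missingness pattern, restricted to groups of at least 1,000
members — below that, the Monte-Carlo error of an empirical correlation
(~(1−r²)/√n ≈ 0.01 at n = 500) would dominate the quantity being
checked.

## Numerical choices and degenerate inputs

- Correlation clipping at |ρ| ≤ 0.9999; likelihood cell probabilities
  floored at 1e−300; effective ±∞ at 12 on the standard-normal scale.
- Scalar likelihood optimizations: bounded Brent, xatol 1e−6 (2e−5 for
  per-observation polychoric likelihoods, whose statistical error is
  orders of magnitude larger).
- Eigenvalue-clipping PSD repair at floor 1e−6, then unit-diagonal
  rescale.
- MINRES uniqueness floor 1e−4; hitting it flags the item as Heywood.
- Constant items, empty pairwise intersections, rank-deficient covariate
  or design matrices, non-positive score variances and non-positive df
  all raise informative errors rather than propagating NaNs.
- Factor alignment for evaluation uses Hungarian assignment on absolute
  Tucker congruence (brute-force enumeration is the test oracle at
  small t); sign ambiguity is resolved per factor.

## Design decisions

- Uniquenesses in the CFA derived from the unit diagonal rather than
  free: enforces the decomposition exactly, halves the parameters, and
  makes "negative uniqueness" a sharp, detectable event.
- Two-step rather than full-ML polychorics: orders of magnitude cheaper
  at biobank scale and standard practice; validated by recovery tests.
- DWLS weights from delta-method/observed-information asymptotic
  variances of each pairwise estimate; these are this package's own
  documented construction, validated by parameter recovery rather than
  by matching any external implementation.
- Pipeline re-runs are idempotent by determinism (same seed, same
  config ⇒ byte-identical outputs); no stage cache is kept.
- The package is a library: the public API plus `examples/` scripts are
  the interface, and `run_pipeline` is the one-call orchestration.

## Known limitations

- No scale-shifted test statistic; chi-square-based indices are on the
  uncorrected DWLS scale and should be compared within, not across,
  weighting schemes.
- Polychoric pairs with per-observation covariate shifts cost ~0.5 s per
  pair at n ≈ 16,000; with thousands of categorical items a marginal
  (offset-free) approximation or subsampling would be needed.
- No imputation path: pairwise deletion throughout (the two approaches
  produce nearly identical correlation matrices when missingness is
  ignorable, which is exactly when both are valid).
- Logistic separation handling is detection-and-flag, not penalized
  estimation.
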