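# Methods

This note documents the models and procedures implemented in `stoichdiet`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not establish.

## Covariate construction

Per-capita nutrient intakes are computed from two tidy inputs: a food-intake
table (country × year × food group, kg/capita/yr, tagged with a source
category) and one or more nutrient-concentration tables (food group × N, P,
protein in g/kg and energy in kcal/kg). For each (country, year, source):

- `N_kg = Σ_g intake_kg(g) × N_g_per_kg(g) / 1000`, and likewise P and
  protein; `kcal = Σ_g intake_kg(g) × kcal_per_kg(g)`; `total_kg = Σ_g
  intake_kg(g)`.
- `N:P` is the **ratio of aggregated sums**, not the mean of per-food ratios:
  at the intake level the stoichiometric ratio of a diet is the ratio of its
  total elemental fluxes. It is flagged undefined (NaN) when `P_kg = 0`, and
  the invariant `N = N:P × P` holds on every emitted row.
- When several concentration databases cover the same food group, the final
  concentration is their per-nutrient arithmetic mean; single-database groups
  pass through unchanged.

Canonical units are kg/capita/yr for N, P and protein and kcal/capita/yr for
energy (helpers convert g↔kg). The panel's 33 columns are the six measures
for terrestrial-animal, vegetable, terrestrial-animal/vegetable (element-wise
quotient), aquatic-animal and alcoholic sources, plus GDP per capita, median
age and HDI.

Two ordering decisions matter and are deliberate:

- **Covariates are formed yearly, then period-aggregated.** The ta/veg
  quotients and N:P ratios are computed per year and the resulting series is
  averaged (mode `mean`) or differenced between the period's last and first
  decades (mode `change`). The alternative — aggregating the measures first
  and taking quotients of aggregates — is unstable in change mode (quotients
  of near-zero decade differences) and answers a different question.
- **Complete-case countries.** Any country with a missing covariate in the
  period (including an undefined ratio from a zero vegetable denominator) is
  dropped with a logged warning, so sample size varies with the period and
  mode exactly as it does in real panels assembled from heterogeneous
  national records.

## Age standardization

Rates are directly standardized: `ASR = Σ_a w_a · 100000 · d_a / n_a` over a
fixed standard population. The default weight table is the WHO World
Standard (18 five-year groups, 85+ open-ended), shipped as
`data/who_world_standard.csv` and renormalized to sum to one on load; the
published source of the weighting scheme is configurable because several
"world standard" tables circulate. A stratum with zero population and zero
deaths contributes rate 0 (with a warning); zero population with positive
deaths is an error. The same operation serves prevalence counts.

## Dimension reduction

The 33 covariates are strongly collinear by construction of the problem
(six measures of the same dietary flux per source). The reduction is:

1. **Distance.** Covariates are standardized (units are incommensurable —
   kg, kcal, unitless ratios — so the covariance scale is the correlation
   scale) and the distance is `1 − |r|`. The absolute value makes the
   distance sign-blind: a strongly negative correlate is exactly as redundant
   for dimension reduction as a positive one.
2. **Clustering.** Agglomerative hierarchical clustering with average
   linkage (UPGMA), the variant the cluster-count criterion below was
   published with.
3. **Cluster count.** The Kelley penalty: at each candidate cut k, the mean
   over multi-member clusters of the mean within-cluster pairwise distance is
   normalized onto [1, n−1] and k is added; the k minimizing the score wins,
   ties broken toward smaller k. The normalization is **anchored** between
   the smallest candidate spread and the trivial one-cluster spread (the mean
   pairwise distance of the whole set). Without the anchor, data whose every
   candidate cut is already tight — e.g. two cleanly separated blocks — have
   meaninglessly small spread differences stretched to the full scale, and
   the criterion over-splits; the anchor makes the score measure how much of
   the total spread a cut leaves unresolved. All-singleton cuts take spread 0
   with a warning.
4. **Per-cluster PCA.** Eigen-decomposition of each cluster's correlation
   matrix; the three leading eigenvectors are retained (fewer if the cluster
   is smaller), a warning is raised if they capture less than 90% of the
   cluster's variance. Eigenvector signs are fixed by making the
   largest-magnitude loading positive, for bit-reproducibility. Factor scores
   are the standardized covariates projected on the loadings; the loadings
   matrix is kept block-structured (zero outside a factor's cluster) so that
   coefficient back-mapping is a single matrix product.

VIF diagnostics (`1/(1−R²)` from regressing each regressor on the others,
with intercept) are provided to verify that the retained factors carry low
residual multicollinearity; exact collinearity reports as infinity.

## Spike-and-slab regression (SSVS)

The regression of each (standardized) response on the factor scores uses
stochastic search variable selection: coefficient j has the mixture prior
`β_j ~ (1−γ_j) N(0, τ0²) + γ_j N(0, τ1²)` with `γ_j ~ Bernoulli(p)`, and
`σ² ~ InvGamma(a, b)`. Defaults, all overridable in `SSVSConfig`: τ0 = 0.01
(a spike that is numerically zero on the standardized scale), τ1 = 10
(diffuse), p = 0.5 (agnostic), a = b = 0.01 (vague), 20,000 draws with 5,000
burn-in and thinning 5. The Gibbs sampler cycles the three full
conditionals: β jointly from `N(A⁻¹X'y/σ², A⁻¹)` with
`A = X'X/σ² + diag(1/τ²_γ)` (Cholesky draw), γ_j from the two-component
posterior odds, σ² from its inverse gamma. With all indicators forced on
(`force_include`) the posterior mean reduces to the ridge estimate
`(X'X + σ²/τ1² I)⁻¹X'y`, which the tests use as a closed-form oracle. Fixed
seed gives identical draws.

Design choices:

- Regressors are standardized internally and responses standardized by the
  pipeline, so priors are scale-free and reported effects are in SD units
  (rescaling helpers: `beta_draws_original`, `conf_int(original_scale=True)`).
- The three controls are clustered together with the nutritional covariates
  and enter through their cluster's factors, subject to selection like
  everything else; `backmap_coefficients` equally supports a design where
  controls are kept outside the clustering and pass through unmapped.
- Significance is operationalized as the 95% equal-tailed credible interval
  excluding zero. No extra multiplicity correction is applied: the
  spike-and-slab prior is itself the shrinkage mechanism, and the all-noise
  false-positive rate is measured by the end-to-end tests (≤ a few percent of
  grid cells) rather than assumed.
- Back-mapping is exact per draw: covariate effect = Σ (loading × factor
  coefficient on the raw factor scale), then summarized. A covariate's
  inclusion frequency is the fraction of draws in which any factor of its
  cluster is in the slab.

## Reduced major axis

`rma_fit` implements the standardized major axis: `slope = sign(r) ·
sd(y)/sd(x)`, line through the centroid; the reported p-value is the
two-sided Pearson correlation test on n−2 df (a permutation alternative is
provided for small n). When r is exactly zero the slope's sign is set
positive and flagged. The fit is symmetric (swapping axes inverts the slope)
and scale-equivariant, appropriate when both axes carry error.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of the real study inputs at
their stated scale — 40 countries, years 1960–2010, six covariates per
source with strong within-source correlation (block correlation 0.85 by
default), five recoverable covariate blocks, sparse linear effects, Poisson
death counts — not their content:

- Within each source, log group intakes follow a one-factor model with
  role-specific loadings: `log I_cg = log m_g + σx(λ_g f_sc + ν ε_cg)`,
  λ_g ∝ √ρ with per-role multipliers (the N-rich group 1.55, the P-rich 0.5,
  others between) and ν ∝ √(1−ρ). Because the N-rich and P-rich groups
  respond differently to the factor, the aggregated N:P ratio co-moves with
  its block — dietary composition shifting with affluence — instead of being
  pure noise. Country-specific growth trends with the same loading structure
  give the change-mode covariates the same block structure.
- Each source's food groups are stylized to be rich in one trait (N, P,
  energy or protein, with balanced fillers); concentration values are
  plausible in magnitude but are **not** nutritionally accurate tables, and
  two concentration "databases" jittered around common means exercise the
  database-averaging path. The alcoholic source defaults to three beverage
  groups: a single group would make its N:P covariate constant across
  countries (zero variance), which the reduction stage must reject.
- GDP, HDI and median age load on the terrestrial-animal factor
  (diet–development coupling), so the controls genuinely confound the diet
  blocks as they do in real country panels, and the 33 covariates form five
  blocks: {terrestrial-animal + controls}, vegetable, ta/veg ratio,
  aquatic-animal, alcoholic.
- Responses are `intercept + scale·(Σ β_j z_j + ε)` on standardized
  covariates, so configured effects are in SD units and recovery thresholds
  scale-free; intercept/scale anchors put prevalence and mortality near
  realistic per-100,000 levels. Mortality responses are optionally pushed
  through the full observation path: an exponential-in-age relative-risk
  profile normalized against the standard weights (so standardizing the
  expanded rates returns the target exactly), development-tilted population
  pyramids, Poisson death counts, then direct standardization.
- Death counts are Poisson, the simplest model consistent with raw count
  data; overdispersion is not modeled by default. Missing-data patterns,
  disease-coding harmonization and country-name reconciliation of real
  databases are deliberately out of scope.

The generator's internal constants (loading multipliers, noise scales,
control coupling) were calibrated once, by pilot simulation, so that the
observable contract holds — mean within-source |r| ≈ the configured block
correlation (0.87–0.95 per source at ρ = 0.85), the Kelley cut selecting
five clusters in ≈95% of seeds with near-perfect membership recovery, and
the three leading eigenvectors capturing ≥94% of within-cluster variance —
and then frozen. Consequently, passing tests show that the *pipeline*
recovers structure and effects under the stated conditions; they do not
validate nutritional content, real-world effect sizes, or robustness to the
messiness (missingness, coding changes, overdispersion) of real mortality
databases.

## Problem sizes used by the test suite

Operating-characteristic and recovery checks are run at the study's own
scale: 40 countries × 51 years for panels, n = 200 × 10 regressors × 100
seeds for sampler calibration (coverage between 90% and 98%), 100 seeds for
cluster-count recovery, and six-seed end-to-end recovery runs with a
shortened chain (8,000 draws, 2,000 burn-in, thinning 3) whose inclusion
frequencies are stable at that length. The acceptance script uses 20
replicate panels.

## Known limitations

- The Kelley criterion's anchored normalization is a package-level
  formulation choice (the criterion circulates without a canonical formula);
  on pathological dendrograms other anchors could select different k.
- Back-mapped effects of covariates within one collinear block are not
  separately identified — by design the method attributes effects to blocks;
  the worked example in the README shows exactly this behavior.
- The SSVS sampler is a dense Gibbs sampler adequate for tens of regressors
  and hundreds of rows; it is not built for thousands of covariates.
- With strong diet–development coupling, control covariates sharing a block
  with diet covariates inherit significance through the loadings; this is the
  honest confounding structure of country-level data, not an artifact.
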