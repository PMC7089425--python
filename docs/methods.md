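# Methods

This note documents the statistical machinery in `spatreg`: the models and
their assumptions, the numerical choices that a maintainer would otherwise
have to reverse-engineer, what the synthetic-data generator does and does
not emulate, and known limitations.

## Spatial linear model

The SLM assumes a Gaussian response with a stationary, isotropic
exponential covariance in planar Euclidean distance:

    Y = Xβ + z + ε,   cov(z(s_i), z(s_j)) = σ²_z exp(−‖s_i − s_j‖/α),
    var(ε) = σ²_ε I.

Assumptions: second-order stationarity, isotropy, exponential decay, and a
planar coordinate system (geographic data must be projected, e.g. to an
equal-area CRS in km, before input — the package performs no projection).
Other covariance families (Matérn, spherical), anisotropy, and
network-distance models are out of scope.

### Estimation

β is profiled out of the likelihood by its GLS solution, leaving a
3-parameter optimization over θ = (σ²_ε, σ²_z, α). Numerical choices:

* **Parameterization.** Optimization runs unconstrained over
  (log σ²_ε, log σ²_z, log α). Zero variances are approached only in the
  limit; a fit is reported as "no spatial component" when the partial sill
  is negligible relative to the total sill.
* **Initial values.** Nugget and partial sill each start at half the OLS
  residual variance; the range starts at one quarter of the maximum
  pairwise distance.
* **Optimizer.** Nelder–Mead with objective tolerance 1e-6 (maxiter 2000);
  one restart from perturbed initial values if the first attempt fails.
  Any robust local optimizer would do; the parameter-recovery test (REML,
  n = 500, 20 replicates, median relative error < 50% per parameter)
  defines the bar.
* **REML vs ML.** REML adds c = −p log 2π + log|X'Σ⁻¹X| to the profiled
  deviance. Final fits use REML (less bias when p is non-trivial relative
  to n); the selection loop uses ML because AIC comparisons across
  different fixed-effects sets are only valid under ML.
* **Model complexity.** AIC = 2·(negative log-likelihood) + 2·(p + 3): the
  fixed effects plus the three covariance parameters. An intercept-only
  (ordinary-kriging) model therefore has k = 4.

### Reduced-rank covariance

With r knot locations, Σ = S K⁻¹S' + σ²_ε I, where S (n×r) and K (r×r)
hold exponential covariances to and among the knots. The
Sherman–Morrison–Woodbury identity gives
Σ⁻¹ = σ⁻²_ε [I − S(σ²_ε K + S'S)⁻¹S'], and the matrix determinant lemma
gives log|Σ| = n log σ²_ε + log|K + σ⁻²_ε S'S| − log|K| — the determinant
companion is required by the likelihood even though only the inverse is
usually quoted. Both use only r×r Cholesky factorizations; an inner matrix
with condition number above 1e12 raises with the condition number in the
message. With knots equal to the data locations, S = K = R and the
reduced-rank likelihood equals the dense one (tested to 1e-8 relative).
Default knots: k-means centroids of the coordinates, r = min(100, n/5),
fixed seed, user-overridable. Duplicate data locations are allowed whenever
the nugget is positive; a zero-nugget model with duplicates is singular and
warns.

### Prediction

Universal kriging (mean and variance as in the README) with
C(s₀, s₀) = σ²_z + σ²_ε: a *new* site carries its own nugget, so intervals
target the observable response rather than the smooth surface — this is
what makes interval coverage near-nominal. Coincident prediction sites
(distance exactly 0 to a training site) include the nugget in the
cross-covariance, making kriging an exact interpolator there. Predictions
are chunked so the n×m cross-covariance stays below a configurable budget.
Simple kriging is the zero-mean special case (no trend-uncertainty term),
used for residual fields. Negative computed variances beyond −1e-8 raise;
smaller negative round-off is clipped to zero. Clamping predictions to a
bounded response scale (e.g. 0–100 indices) is off by default and reported
with a count when enabled.

## Covariate transformations

Each covariate competes independently over a grid:
λ₁ ∈ {0, 0.25, 0.5, 1, 1.5, 2, 3} and λ₂ ∈ {0, 1, half the smallest
positive value}, filtered so x + λ₂ > 0 on the training support. A
covariate is zero-inflated when strictly more than 2% of values are exactly
zero; its Box-Cox terms are evaluated on the nonzero support only and
multiplied by the indicator, so λ₂ = 0 is admissible when the nonzero
support is positive. Candidates are scored by OLS — spatial correlation is
deliberately ignored at this stage for speed; it biases selection little
because only within-covariate comparisons matter — with the Gaussian
profile AIC n log(RSS/n) + 2(k+1). Ties break deterministically toward
smaller λ₁, then the simpler form. Covariates are not standardized: Box-Cox
is scale-sensitive and raw scales are preserved. Prediction-time data
reuse the frozen (form, λ₁, λ₂); region labels unseen in training are an
error.

Identifiability caveat: on narrow covariate supports many (λ₁, λ₂)
combinations are near-affine transformations of one another, so the
*selected exponent* is only weakly identified even when the *form*
(linear vs quadratic vs indicator) is stable. The recovery tests therefore
assert exponent recovery only for well-separated exponents (log and
identity) on a wide support, and form recovery elsewhere.

## Covariate selection

Phase 1: greedy backward elimination on the non-spatial LM — at each step
remove the single column whose removal lowers AIC most, stop when no
removal lowers AIC. Phase 2: fit the SLM by reduced-rank ML, repeatedly
remove the candidate with the **smallest** absolute t-statistic and accept
the removal only if AIC does not increase; covariance parameters are
warm-started between refits; the final model is refit by full-rank REML.

Note: descriptions of this procedure sometimes say "largest absolute
t-statistic". Removing the *most* significant covariate would contradict
backward elimination and could not produce a smaller, well-fitting model;
this implementation removes the least significant candidate and flags the
reading here deliberately.

The intercept and region dummies are always protected. Two-column
transformations obey weak hierarchy: the quadratic (or Box-Cox) column must
leave before its base (linear or indicator) column becomes removable.

## Forests, QRF, RFRK

Trees are CART regression trees grown on bootstrap samples with mtry
candidate covariates per split. `min_node_size = 5` follows the classical
regression-forest convention: nodes with at most 5 cases become terminal,
larger nodes keep splitting (children may be smaller) — mapping it to a
minimum *leaf* size instead grows visibly shallower trees and worsens
test error on the benchmark. One master seed fans out per-tree bootstrap
and split seeds.

QRF weights use bootstrap multiplicities: w_i(x₀) averages, over trees, the
count of bootstrap copies of observation i in the leaf containing x₀,
normalized by the leaf's bootstrap size. This makes the forest mean exactly
the weight-averaged training response (tested to 1e-8). Quantiles invert
the weighted empirical CDF left-continuously,
Q̂_α = inf{y_i : Σ w_i 1{y_i ≤ y} ≥ α}; the convention matters because
right-continuous or interpolated inversions widen or narrow intervals.

RFRK fits a zero-mean ML simple-kriging model to the forest's **out-of-bag**
residuals y_i − f̂_OOB(x_i) and predicts f̂_RF(x₀) + ê(s₀) with intervals
mean ± z·(SK standard error). In-bag residuals are not used: the forest
partially memorizes in-bag responses, so in-bag residuals understate the
residual variance and produced ~0.70 coverage for nominal 90% intervals in
pilot runs; OOB residuals restore near-nominal coverage. A perfectly
predictable response (zero residual variance) skips the kriging stage.
Permutation importance is the mean over trees of the OOB MSE increase after
permuting one covariate.

## Synthetic data

The generator draws 1500 locations uniformly on the unit square, four
i.i.d. Unif[0,1] covariates, and

    y(s) = c [ a sin(5π x₁x₂) + 2x₃ − x₄ ] + δ(s),

with δ = z + ε, z an exponential-covariance Gaussian field (α = 0.5) drawn
by dense Cholesky factorization (1e-10 ridge retry on failure) and ε
i.i.d. nugget noise. Per realization, `a` is solved by 1-D root finding so
the empirical variance share var(a·g)/var(a·g + h) hits its target (0.9 or
0.1; empirical variances, cross-terms retained in var(f) — this definition
reproduces the reference run-averaged values a ≈ 2.94 and 0.33), then `c`
is set to sqrt(R²/(1−R²) · var(δ)/var(f)). δ is residualized against
(1, f) in-sample first, so the empirical R² = var(c·f)/var(y) equals its
target exactly per run (an O(1/√n) perturbation of the field; a switch
disables it). Calibration order — a first (shape), then c (scale) —
mirrors the per-run protocol. The eight study conditions cross
nonlinearity share, R², and (nugget, partial sill) ∈ {(9,1), (1,9)};
500 points train, 1000 test.

What the generator does *not* emulate: the skewness, zero-inflation, and
spatial structure of real landscape covariates (covariates here are
uniform and spatially unstructured), measurement error in the response
scale, and preferential sampling. Passing benchmark tests therefore shows
correctness of the estimators under a known model, not performance on any
particular survey data set.

## Evaluation

RMSPE is √mean((Y−Ŷ)²); interval coverage uses strict inequalities, so a
boundary observation counts as non-covered. Cross-validation uses a
uniform random K-fold partition (not spatially blocked) with the entire
recipe — transformation estimation, selection, fitting — re-run inside
every fold. The non-spatial LM's intervals are classical normal-theory
prediction intervals (± z·se including residual variance) with z = 1.645
at 90% and 1.960 at 95% (printed-constant convention; other levels use the
exact normal quantile). The benchmark harness fans a master seed out to
(case, run) seeds via `SeedSequence`, reports means with standard errors
SD/√runs, and shares one fitted forest between the RF and RFRK arms of a
run.

### Problem sizes used by the shipped tests

Benchmark cells compared against published means run at the study's own
conditions: 20 replicates, 500 training / 1000 test points. The
qualitative-ordering sweep across all eight cases runs 6 replicates per
case — the orderings it checks are separated by many standard errors, so
6 replicates decide them reliably while keeping the suite fast. Unit tests
use n between 20 and 500.

## Known limitations

* Exponential covariance only; range and partial sill trade off on domains
  shorter than the range (weak identifiability), which inflates those two
  parameters jointly without much harming prediction.
* No standard errors for covariance parameters; no Bayesian machinery.
* Reduced-rank approximations over-smooth when r is far too small;
  the default knot rule is a heuristic, not an optimality claim.
* The stepwise selection inherits AIC's known ~16%-per-column chance of
  retaining a pure-noise covariate; it is a parsimony device, not an
  error-controlled test.
* QRF intervals are wider and more variable in length than kriging
  intervals and may over-cover when the signal is strongly linear.
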