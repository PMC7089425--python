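# spatreg

Spatial linear models versus random forests for large environmental data
sets: geostatistical regression with universal kriging, an AIC-driven
Box-Cox covariate-transformation and selection pipeline, quantile regression
forests, random forest regression kriging, and a simulation benchmark that
pits the approaches against each other on spatially autocorrelated data.

## Who this is for

Analysts modelling a continuous environmental response observed at point
locations — stream-condition indices, soil properties, pollutant loads —
with many candidate covariates, who need both accurate point predictions
and honest prediction intervals, and who want to know *when* a carefully
built spatial regression beats an off-the-shelf forest (and vice versa).

## The models

**Spatial linear model (SLM).** For a response Y observed at planar
locations s_i,

    Y = Xβ + z + ε,      Σ = var(Y) = R + σ²_ε I,
    R_ij = σ²_z exp(−‖s_i − s_j‖ / α),

with nugget σ²_ε, partial sill σ²_z and range α. Covariance parameters are
estimated by ML or REML on the profiled negative log-likelihood

    ℓ(θ) = ½{ n log 2π + log|Σ(θ)| + r'Σ(θ)⁻¹r + c },

where r = Y − Xβ̂(θ), β̂(θ) = (X'Σ⁻¹X)⁻¹X'Σ⁻¹Y, and c adds the REML
design term. Predictions at new sites use the universal-kriging equations

    Ŷ(s₀) = x₀'β̂ + c₀'Σ⁻¹(Y − Xβ̂),
    var(Ŷ(s₀)) = C(s₀,s₀) − c₀'Σ⁻¹c₀ + t₀'(X'Σ⁻¹X)⁻¹t₀.

For large n, a reduced-rank covariance Σ = S K⁻¹S' + σ²_ε I built from r ≪ n
knots is inverted with the Sherman–Morrison–Woodbury identity, so only
r × r factorizations are performed.

**Covariate transformations.** Skewed and zero-inflated covariates are
linearized per covariate with shifted Box-Cox powers
g(x; λ₁, λ₂) = ((x+λ₂)^λ₁ − 1)/λ₁ (log for λ₁ = 0), choosing the form and
(λ₁, λ₂) by AIC over a grid: indicator / indicator×g / both for
zero-inflated covariates (> 2% exact zeros), linear or quadratic in g
otherwise. Selection is two-phase: backward stepwise AIC on the non-spatial
LM, then t-statistic-guided backward elimination with reduced-rank ML SLM
refits, finishing with a full-rank REML fit.

**Forests.** A bagged CART ensemble (1000 trees, mtry = ⌊p/3⌋, node size 5)
with quantile-regression-forest intervals: each training response gets
weight w_i(x₀) = (1/B) Σ_b m_ib(x₀)/|leaf_b(x₀)| and intervals are weighted
empirical quantiles [Q̂_.05, Q̂_.95]. Random forest regression kriging
(RFRK) adds simple kriging of the forest's out-of-bag residual field and
uses the kriging variance for intervals.

## Worked example

```python
import numpy as np
from spatreg import SpatialLM, generate_case

sim = generate_case(6, seed=0)          # linear-dominant, strong autocorrelation
train, test = sim.split()
X = np.column_stack([np.ones(500), train[["x1", "x2", "x3", "x4"]]])
fit = SpatialLM(train["y"], X, train[["x", "y_coord"]],
                exog_names=["Intercept", "x1", "x2", "x3", "x4"]).fit(method="reml")
print(fit.summary())
X0 = np.column_stack([np.ones(1000), test[["x1", "x2", "x3", "x4"]]])
pred = fit.predict(test[["x", "y_coord"]], X0, level=0.90)
inside = np.mean((pred.lower < test["y"]) & (test["y"] < pred.upper))
print(f"test RMSPE {np.sqrt(np.mean((test['y'] - pred.mean)**2)):.3f}, "
      f"90% coverage {inside:.3f}")
```

prints

```
Spatial linear model (exponential covariance)
  method: REML  rank: full  n: 500  converged: True
  -loglik: 923.6870  AIC: 1863.3739  k: 8
  nugget: 1.1080  partial sill: 18.4469  range: 0.8977
  nugget-to-sill: 0.0567
  effective range (0.01): 4.0815
           estimate     se       t
Intercept    0.1273 2.9254  0.0435
x1          -0.5512 0.2056 -2.6816
x2           0.0358 0.2105  0.1700
x3           3.2550 0.2117 15.3767
x4          -1.7734 0.2144 -8.2732
test RMSPE 1.291, 90% coverage 0.922
```

The true linear covariates x3 and x4 dominate the coefficient table
(generating slopes 2 and −1 scaled by the calibration constant c ≈ 1.5);
the fitted nugget recovers the generating value 1, while the partial
sill and range trade off upward together — a known weak identifiability of
the exponential model on a domain shorter than the range, which barely
affects prediction: held-out RMSPE is 1.29 against a response SD of about
3.3, and 90%-interval coverage is near nominal.

The simulation benchmark itself is one call (or `spatreg simstudy` from the
shell):

```python
from spatreg import run_simulation_study
rmspe, coverage90, constants = run_simulation_study(cases=[2, 6], n_runs=20, seed=42)
```

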