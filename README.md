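# censmix

Finite mixtures of linear mixed-effects models for **left-censored
longitudinal data**.

Repeated biomarker measurements — HIV viral loads being the motivating
example — often combine three awkward features at once: latent subgroups of
individuals whose trajectories differ in shape, within-individual
correlation, and a lower limit of detection below which the assay only
reports "≤ limit".  `censmix` fits the model class that addresses all
three:

    Y_i = X_i α_g + Z_i β_i + e_i,          g ~ Categorical(π_1, …, π_G)
    β_i ~ N(0, Ψ_g),   e_i ~ N(0, σ²_g I)

where individual *i* belongs to one latent component *g* for all of its
n_i measurements, X_i is an intercept + B-spline basis in time (so the
trajectory shapes are learned, not assumed), and left-censored responses
enter the likelihood through the multivariate-normal CDF rather than being
imputed.  Estimation is by an EM algorithm whose E-step is fully closed
form: conditional moments of the censored block are truncated
multivariate-normal moments, needing only normal CDFs of dimension d, d−1
and d−2.  The package provides:

- exact, deterministic truncated-MVN moment primitives (`censmix.tmvn`);
- multi-start EM with variance-equality constraints (`censmix.em`);
- AIC/BIC model-grid and two-stage constraint selection (`censmix.selection`);
- empirical-information standard errors via analytic scores, and pointwise
  confidence bands for component means (`censmix.inference`);
- a synthetic-data generator with the model's exact structure, component
  matching, adjusted Rand index and a parametric-bootstrap harness
  (`censmix.simulate`);
- a statsmodels-style model/results surface (`CensoredLMMixture`) and a
  `censmix` command line (`fit`, `select`, `infer`, `simulate`,
  `bootstrap`).

## Worked example

Simulate a viral-load-like trial from the built-in two-component design
(log₁₀ scale, detection limit 2.0 = 100 copies/ml, ~20% censored) and fit
it from a long-format data frame:

```python
import numpy as np
from censmix import CensoredLMMixture, simulate_dataset, two_component_design
from censmix.io import dataset_to_frame

data, truth = simulate_dataset(two_component_design(N=100, seed=42))
df = dataset_to_frame(data)          # columns: id, time, y, cens

model = CensoredLMMixture.from_dataframe(df, n_components=2, spline_df=2)
res = model.fit(n_starts=3, seed=1)
print(res.summary())
```

```
Finite mixture of censored linear mixed models
==============================================================
components: 2    individuals: 100    free parameters: 11
log-likelihood: -700.9872    AIC: 1423.97    BIC: 1452.63
converged: True after 35 iterations
--------------------------------------------------------------
parameter                 estimate       std err
pi[0]                       0.5749        0.0520
alpha[0][0]                 4.5256        0.0729
alpha[0][1]                -4.0714        0.1702
alpha[0][2]                -3.4870        0.1640
alpha[1][0]                 4.0927        0.0734
alpha[1][1]                -3.9466        0.2180
alpha[1][2]                -0.9115        0.1005
sigma2[0]                   0.2685        0.0240
sigma2[1]                   0.2910        0.0233
Psi[0][0,0]                 0.2054        0.0462
Psi[1][0,0]                 0.1302        0.0347
==============================================================
```

The generating design has weights (0.55, 0.45), spline coefficients
(4.5, −4.0, −3.5) and (4.3, −4.1, −1.0), residual variance 0.3025 and
random-intercept variance 0.16 — every estimate above lands within about
two standard errors of its generating value.  `pi[0]` is the estimated
share of the declining-and-staying-low subgroup; the `alpha` rows describe
each component's mean trajectory on the spline basis; `sigma2` and `Psi`
are the within- and between-individual variances.  Pointwise 95% bands for
a component mean:

```python
lo, mid, hi = res.mean_band(0, [0.0, 28.0, 168.0])
# lo  = [4.38 3.15 0.69]
# mid = [4.53 3.30 1.04]
# hi  = [4.67 3.44 1.39]
```

Model selection over the full grid (components × spline flexibility ×
variance constraints), and posterior cluster assignments:

```python
from censmix import ModelGrid, fit_grid
sel = fit_grid(raw_data, ModelGrid(G_values=(1, 2, 3)), control)
sel.table           # one row per model: loglik, k, AIC, BIC
res.assignments     # maximum a posteriori component per individual
```

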