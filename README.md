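# gwtls

**Geographically weighted total least squares regression (GWTLSR) for
errors-in-variables land-use regression.**

Land-use regression (LUR) predicts a pollutant concentration (here PM2.5,
µg/m³) at monitoring stations from spatial covariates — traffic volume in
buffers, residential/non-residential land-use shares, meteorology. Two
things routinely violate the assumptions of the ordinary least squares
(OLS) fit used in most LUR studies:

1. **Spatial nonstationarity** — the regression coefficients themselves
   vary over the city. Geographically weighted regression (GWR) handles
   this by solving a weighted least-squares problem at every location, with
   Gaussian distance-decay weights
   `w(d) = exp(−d²/b²)` and bandwidth `b`.
2. **Errors in variables (EIV)** — the covariates are themselves measured
   or modelled, with known (or assumed) per-cell variances δ²ᵢₖ. Weighted
   total least squares (WTLS) estimates the coefficients while attributing
   error to both the design matrix `A` and the observations `y`.

GWTLSR fuses the two: at each regression point the WTLS problem

    y = (A − E_A) x + e_y,   Q_y = W(u,v)⁻¹,   Q_A = diag(δ²ᵢₖ)

is solved by a Lagrangian fixed-point iteration (initialized at OLS):

    Q_ỹ = Q_y + (x̂ᵀ⊗I_m) Q_A (x̂⊗I_m)
    λ̂  = Q_ỹ⁻¹ (y − A x̂)
    ẽ_A = −Q_A (x̂ ⊗ I_m) λ̂
    x̂  = ((A−Ẽ_A)ᵀ Q_ỹ⁻¹ (A−Ẽ_A))⁻¹ (A−Ẽ_A)ᵀ Q_ỹ⁻¹ (y − Ẽ_A x̂)

yielding spatially varying, attenuation-corrected coefficient surfaces.
The package implements the full estimator family (OLS, GWR, WTLS, GWTLSR),
AICc-driven bandwidth selection, model assessment (R², RMSE, MAE, AICc,
POD/POF exceedance verification, residual Moran's I), two-stage variable
selection, leave-one-station-out cross-validation, and a synthetic-data
generator with known ground truth for validating all of it. It is aimed at
exposure-assessment and spatial-epidemiology practitioners working with
sparse monitoring networks.

## Worked example

Simulate a 9-station campaign (30 daily samples per station, three noisy
covariates, spatially varying coefficients) and compare the three models:

```sh
$ gwtls simulate --seed 42 --out demo
wrote demo/stations.csv (270 samples, 9 stations) and truth table

$ gwtls compare --input demo/stations.csv --out demo/compare.csv
 model       r2      rmse       mae        aicc  sigma_hat  hat_trace      pod      pof  morans_i  morans_z  morans_p morans_pattern
   ols 0.227474 17.987985 15.889987 2336.894258  17.987985   4.000000 0.037037 0.500000  0.135744  2.478031  0.013211      Clustered
   gwr 0.970531  3.513233  2.799024 1520.557001   3.513233  32.111877 0.740741 0.200000 -0.332621 -2.084599  0.037106     Dispersed
gwtlsr 0.954003  4.389251  3.405674 1619.287206   4.389251  23.584044 0.740741 0.285714 -0.336513 -2.069450  0.038504     Dispersed
```

Reading the output: the global OLS fit cannot follow the spatially varying
coefficients (R² = 0.23) and its per-station mean errors are significantly
spatially clustered (Moran's I = 0.14, z = 2.5). The local models explain
most of the variance (R² ≈ 0.95–0.97, in-sample), detect most
exceedances of the 90th-percentile threshold (POD = 0.74 versus 0.04), and
remove the clustering — in this particular draw their station-mean errors
land just past the opposite significance cut (z ≈ −2.07, "Dispersed", a
borderline outcome; over many draws the modal pattern is "Random").
`hat_trace` is the effective number of parameters of the local fit, which
drives the AICc comparison.

Held-out performance (the honest comparison) comes from station-wise
cross-validation:

```sh
$ gwtls cv --input demo/stations.csv --model gwtlsr
9 folds; means: rmse_test=8.0275, rmse_train=4.3020, mae_test=7.0177, mae_train=3.3436
```

The library mirrors the CLI one-to-one:

```python
from gwtls import SimulationConfig, generate, gwtlsr_fit, select_bandwidth

ds = generate(SimulationConfig(seed=42))
system = ds.design_system()
b = select_bandwidth(system, model="gwr").bandwidth
fit = gwtlsr_fit(system, bandwidth=b)
print(fit.coefficient_table()[:2])  # local coefficients, intercept last
```

## Layout

- `src/gwtls/linear_models.py` — DesignSystem container and the four estimators
- `src/gwtls/kernels.py` — Gaussian kernel, AICc bandwidth selection
- `src/gwtls/metrics.py` — R²/RMSE/MAE, AICc, POD/POF, Moran's I
- `src/gwtls/variable_selection.py` — Pearson screen, subset search, station-wise CV
- `src/gwtls/synthetic_data.py` — ground-truth simulator and recovery studies
- `src/gwtls/io.py`, `src/gwtls/cli.py` — station-table IO and the `gwtls` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
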