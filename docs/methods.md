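# Methods

## Model family

All four estimators share one representation of the regression problem: an
m × n design matrix `A` whose first k columns are covariate values and
whose **last** column is the intercept constant 1, an observation vector
`y`, per-cell design variances `Q_A = diag(δ²ᵢₖ)` (column-major over `A`,
intercept block identically zero), and a diagonal observation covariance
`Q_y`.

**OLS** solves `x̂ = (AᵀA)⁻¹Aᵀy` with identity weights. **GWR** solves the
weighted normal equations at each regression point with fixed Gaussian
kernel weights `wₖ = exp(−d²ₖ/b²)`, `d` the Euclidean distance on projected
(metric) coordinates; geographic coordinates must be projected before use.
**WTLS** admits error in both `A` and `y` and minimizes

    φ = e_yᵀ Q_y⁻¹ e_y + e_Aᵀ Q_A⁻¹ e_A
    subject to  y = (A − E_A)x + e_y.

The Lagrangian stationarity conditions give a fixed-point cycle
(combined covariance `Q_ỹ = Q_y + Σⱼ x̂ⱼ² diag(qa_j)`, multipliers
`λ̂ = Q_ỹ⁻¹(y − Ax̂)`, design errors `Ẽ_A[:,j] = −x̂ⱼ qa_j λ̂`, then a
generalized least-squares update of `x̂` on the corrected system),
initialized at OLS. Because `Q_A` is diagonal, the nominally mn × mn
Kronecker algebra collapses to O(mn) column-wise operations per iteration.
Eliminating the design errors analytically shows the fixed point is a
stationary point of the profiled objective
`φ(x) = (y − Ax)ᵀ Q_ỹ(x)⁻¹ (y − Ax)`; the test suite verifies agreement
with a derivative-free minimizer of this profile to 1e−6 on small random
systems.

**GWTLSR** runs the same cycle at each regression point with
`Q_y = W(u,v)⁻¹` — the inverse kernel weights — so distant samples carry
large observation variance, while the full `Q_A` carries the covariate
measurement error. This simultaneously corrects the attenuation bias that
EIV induces in local slopes (and the compensating intercept bias, which
dominates when covariate means sit far from zero) and lets the coefficient
field vary over space. Note the scale convention: `Q_y` equals 1 at the
regression point itself, so the balance between observation and design
error is set entirely by the δ² values supplied.

A one-shot variant (`mode="one_shot"`) applies a single design-error
correction to the local GWR solution followed by one corrected solve; it
is a first-iteration approximation of the full cycle and is exposed
because either reading of the estimator is plausible. The default is full
iteration.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bandwidth` (m) | AICc-selected | Gaussian kernel scale; weight `e⁻¹` at `d = b` |
| search bounds | 0.1×–10× max pairwise distance | log-scale golden-section bracket |
| `tol` | 1e−10 | relative ∞-norm coefficient change declaring convergence |
| `max_iter` | 100 | WTLS iteration cap; the linear fixed-point rate can want 10³ near weak identification |
| weight floor | 1e−12 | kernel weights are clamped before inversion into `Q_y`; keeps far-from-data local problems well posed |
| exceedance percentile | 90 | POD/POF threshold, linear-interpolated over the observed series |
| significance cut | \|z\| = 1.96 | Moran pattern labels Clustered/Random/Dispersed |

Bandwidth selection minimizes `AICc(b) = 2n ln σ̂ + n ln 2π +
n(n + tr S)/(n − 2 − tr S)` with σ̂ = √(RSS/n) (the maximum-likelihood
scale, under which the expression is the standard local-regression AICc)
and `S` the hat matrix assembled row-wise from the local solves. For
GWTLSR the hat rows use the corrected design `A − Ẽ_A` and the final
`Q_ỹ⁻¹` weights. Ties (e.g. a degenerate perfect fit at every bandwidth,
where σ̂ = 0 maps to AICc = −∞) break toward the smallest admissible
bandwidth evaluated. A caveat observed in simulation: with many repeated
samples per station, `tr S` stays far below n and AICc is monotone down to
the lower search bound — effectively choosing per-station local models;
see Limitations.

Moran's I uses row-standardized inverse-Euclidean-distance weights with
zero diagonal (coincident locations floored at half the smallest positive
distance, with a warning) and the analytic Cliff–Ord randomization
moments for the z-score. Simulated null calibration at n = 9 gives a 5.6%
two-sided rejection rate at 1.96, so the analytic approximation is
adequate even for small networks; an exhaustive/sampled permutation check
of the null mean −1/(n−1) is in the test suite.

## Variable selection and validation

Stage one ranks candidates by Pearson correlation with the response; when
a base variable appears at several buffer radii (`traffic_150`,
`traffic_300`, …) only the radius with the highest |r| survives, ties
breaking toward the smaller radius and then the lexicographically smaller
name (both logged). Stage two enumerates all subsets up to five variables
(exhaustive; capped at 12 candidates), fits each by OLS, discards subsets
containing a slope with p > 0.05 *in that subset's own fit* (a variable
may be significant in one subset and not another), and keeps the highest
R². The RMSE-versus-size profile is reported over all enumerated subsets
before the significance filter, where nesting makes it non-increasing.

Model validation is leave-one-station-out: one fold per station, training
on all samples of the other stations and testing on every sample of the
held-out one. Local models predict at the held-out station by refitting
local coefficients at its coordinates (standard local-regression
practice); predictions always use the raw, uncorrected covariate rows.

## Synthetic data

The generator emulates a data-sparse urban campaign: by default 9 stations
placed uniformly in a 20 km square, 30 samples per station, three
covariates at distinct scales (traffic proxy 50 ± 15, residential share
30 ± 10, temperature 18 ± 6) observed with measurement noise at 30% of
each feature's sd (the exact δ² is written to the `__var` columns),
coefficient surfaces that are linear trends spanning ±50% of their mean
across the region (slopes 0.4, 0.6, −0.5 along different directions; the
intercept a ±50% trend around 30 µg/m³ — a spatially varying baseline
concentration), and 2 µg/m³ additive observation noise. These scales put
the total unexplained residual around 3–4 µg/m³, a realistic magnitude
for daily-mean PM2.5 models, and make the nonstationary signal (±10 µg/m³
across the region) clearly dominant over noise. The sample count per
station is kept at 30 (a real seasonal campaign would have hundreds) so
that replicated studies run in seconds; conclusions about estimator
*ordering* are insensitive to this, but absolute error levels are not.

What the generator deliberately does **not** emulate: temporal
autocorrelation across days, day-shared meteorology (every cell is drawn
i.i.d., whereas real temperature columns are nearly constant across
stations within a day), buffer-overlap correlation between land-use
covariates, and non-Gaussian noise. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
model, not performance guarantees on any real monitoring network.

All randomness flows from a single seed through four named child streams
(placement, features, feature noise, observation noise), so each component
can be held fixed independently. The bookkeeping identity
observed = truth + realized noise holds exactly and is asserted in tests.

`recovery_study` draws replicate datasets, fits any subset of the
estimators, and scores (a) RMSE of the estimated local coefficient vectors
against the true coefficient field and (b) leave-one-station-out
prediction RMSE. Under the defaults (20 replicates), mean coefficient
RMSE orders GWTLSR < GWR < OLS: OLS pays for ignoring nonstationarity,
GWR for the EIV attenuation that GWTLSR corrects.

## Numerical choices and degenerate inputs

- Rank-deficient (weighted) normal equations raise a diagnosable error
  naming the dependent columns (identified by pivoted QR of the Gram
  matrix) and, for local fits, the regression point.
- `gwr_fit` raises per-point when fewer than n samples carry weight above
  the floor (true zero weights make the local system singular);
  `gwtlsr_fit` instead relies on the weight floor, which converts
  underflow into a finite huge variance and keeps the solution defined.
- Non-convergence of the WTLS cycle returns an honest `converged=False`
  with a warning rather than raising; with heavy design noise and few
  samples the profiled objective can lose its interior minimum (the TLS
  infimum escapes to infinite slope), which surfaces as drift and is the
  expected failure mode of the model itself, not of the solver.
- POD is undefined (raised) when the observed series never exceeds the
  threshold; POF is defined as 0 when no exceedance is ever estimated.
- AICc is undefined (raised) when `tr S ≥ n − 2`; a perfect fit yields
  −∞ rather than an error so bandwidth ties resolve deterministically.

## Limitations

- The per-location WTLS objective is non-convex; the fixed point reached
  from the OLS start is verified against a global search only on small
  systems. Weakly identified local problems (few effective samples, large
  δ²) may converge to a local stationary point.
- With many repeated samples per station, AICc-driven bandwidth selection
  runs to the lower search bound (per-station models). At such bandwidths
  the EIV-inflated covariance `Q_ỹ` flattens the relative station weights,
  and nearby station pairs cross-contaminate: their mean residuals become
  mildly negatively autocorrelated, occasionally crossing the |z| > 1.96
  cut as "Dispersed" (roughly a quarter of default-regime replicates;
  essentially never "Clustered"). Choosing the bandwidth by held-station
  cross-validation instead of AICc would likely soften this; it is not
  implemented.
- Coordinates are assumed already projected in meters; no geodesy is
  performed. Any planar metric CRS is acceptable.
- Only the fixed Gaussian kernel is provided (no adaptive or compact
  kernels), and no GIS operations (buffer extraction, reclassification)
  or mapping are included: covariates and their variances are inputs.
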