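# Methods

## Model

The package estimates log-linear abundance trends from site-by-year count
data with a three-level hierarchical Poisson model. For site `i` in grid
cell `q(i)` and centered year `t`:

```
N_it ~ Poisson(lambda_it)
log lambda_it = alpha_i + (beta0 + d_i) t + e_it,   e_it ~ N(0, sigma_e)
d_i ~ N(b_q(i), sigma_d)
b_q ~ N(gamma L_q, sigma_b)
```

`alpha_i` is a free intercept per site (sites differ arbitrarily in size
and habitat, so no pooling of levels is attempted — only *trends* are
pooled). The slope of year at a site is `beta0 + d_i`; `d_i` varies
around its cell's mean trend, and cell mean trends vary around a linear
latitude predictor. `b_q + beta0` is the cell-level trend; the
observation-level Gaussian `e_it` makes the counts Poisson-lognormal,
absorbing the extra-Poisson variance that plagues count schemes.

Assumptions worth stating: the trend is log-linear over the analysis
window (a diagnostic checks this, see below); missing site-years are
ignorable given the site (the unbalanced likelihood simply has fewer
terms); latitude is the only cell-level covariate (the hook generalizes —
any per-cell covariate could replace `L_q`); and the latitude covariate is
*not* centered in the reported parameterization, so `beta0` alone is an
extrapolation to latitude 0 and headline numbers always combine
`beta0 + gamma L`.

For fitting, the nested form is reparameterized as
`d_i = gamma L_q(i) + u_q(i) + v_i` with `u_q ~ N(0, sigma_b)`,
`v_i ~ N(0, sigma_d)` — algebraically identical, but it keeps the random
effects centered and lets the optimizer work with independent blocks.

A *preliminary* single-level variant (`log lambda = alpha_i + (mu + s_i) t
+ e_it`) is fitted before any gridding; its per-site slope predictions
feed the spatial diagnosis below.

## Estimation

The marginal likelihood over all random effects is approximated in two
deliberately different ways:

* **Observation effects `e_it` — exact quadrature.** Conditional on the
  structured effects, the `e_it` integrals factorize into one-dimensional
  Poisson-lognormal integrals, one per observation. Each is evaluated by
  20-node adaptive Gauss–Hermite quadrature centered at the conditional
  mode (a strictly concave scalar problem solved by vectorized Newton),
  accurate to ~1e-9 relative. A Laplace step here is the textbook choice
  but biases `sigma_e` down noticeably for counts of this size; the
  quadrature removes that bias and, as a bonus, removes the large `e`
  block from the inner optimization entirely.
* **Slope effects `u, v` — Laplace.** A damped Newton search finds the
  joint mode of the penalized profile log-likelihood over
  `(alpha, u, v)`; the observation block enters through the quadrature
  likelihood and its first two derivatives. The Laplace correction is the
  half log-determinant of the `(u, v)` curvature block, computed via
  sparse LU. Slope effects are informed by whole time series, so the
  Laplace error here is small (verified against 50-node quadrature on
  small designs; the agreement tolerance in the tests is 1e-3 log-units).
* **Site intercepts — REML-style integration.** With hundreds of
  intercepts each informed by ~10 observations, maximizing over them
  (profile ML) gives the classic incidental-parameter bias:
  `E[sigma_e_hat^2] ~ sigma_e^2 (1 - 1/n_bar)`, which simulation showed as
  a 3–4 SE downward shift. The default criterion therefore integrates the
  `alpha_i` under a flat prior — their block joins the log-determinant —
  which removed the bias in parameter-recovery simulations (20/20
  replicates within 2 SE). `reml=False` restores plain profile ML.

The outer optimization is L-BFGS-B over `(beta0, gamma, log sigma_b,
log sigma_d, log sigma_e)` with central-difference gradients
(step 1e-5), warm-started inner solves, and internal latitude centering at
the occupied-cell mean (removing the near-collinearity of `beta0` and
`gamma`; estimates and covariance are mapped back to the raw-latitude
parameterization). Variance parameters live on the log scale with bounds
`log sigma in [-6, 3]`. Standard errors come from a central
finite-difference observed information (step 2e-3) of the profile
objective; SEs for the natural-scale `sigma` are delta-method. Random
effect predictions are posterior modes; their SEs are square roots of the
diagonal of the inverse curvature of the structured block.

Numerical safeguards: the linear predictor is capped at ±30; site
intercepts carry a 1e-8 ridge so all-zero sites stay finite; the inner
Newton accepts steps under an Armijo rule with an absolute slack of
1e-10·|F| (the quadrature objective and its derivatives differ at that
order because node positions move with the linear predictor); inner
convergence targets a gradient of max(1e-9, 1e-12·sum(y)), near the
floating-point noise floor of the data scale, so the outer
finite-difference derivatives see a smooth function.

## Grid standardization and spatial diagnostics

Coordinates are projected with a spherical Lambert azimuthal equal-area
projection (authalic radius, center 52°N/10°E — the European LAEA
convention), implemented in closed form so round-trips are exact. A square
grid (default 75 km) is anchored by flooring the bounding-box minimum to a
cell-size multiple (an explicit origin override exists for matching an
external grid); membership is half-open on both axes, making the
assignment an exact partition. The cell latitude `L_q` is the centroid
latitude of the cell polygon, not the mean of member sites — stable under
site turnover.

Spatial autocorrelation is tested with Moran's I on a relative
neighborhood graph of the (projected) points: `p ~ q` iff no third point
is strictly closer to both. Construction screens Delaunay edges (the RNG
is a Delaunay subgraph and contains the MST, hence is connected); exact
geometric ties do not block an edge (strict inequality with a 1e-12
relative guard); duplicate coordinates are jittered by a configurable
epsilon and logged. Weights are row-standardized by default (binary
available); the test uses the Cliff–Ord closed-form moments, by default
under the randomization null with a one-sided "greater" alternative
(positive autocorrelation is the phenomenon of interest; the variance
formula was verified against R's `ape::Moran.I` to 12 decimals and
against empirical permutation moments).

The pipeline reports Moran tests on both the literal predictions
(`b_hat_q`, `d_hat_i`) and the latitude-detrended deviations
(`u_hat = b_hat − gamma L`, `v_hat = d_hat − b_hat`). The headline
before/after contrast uses the detrended site deviations: the literal
`d_hat` contains the fitted latitude gradient, which is spatially smooth
by construction and can dominate the statistic on small synthetic
landscapes even when the model has captured all residual structure.

## Trend summaries

All headline quantities derive from `m(L) = beta0 + gamma L`:

* percentage decline over `D` years: `r = 100 (1 − exp(D m))`, positive
  numbers meaning decline; `SE(r) = |100 D exp(D m)| SE(m)` with `SE(m)`
  from the `(beta0, gamma)` covariance (these SEs condition on the
  variance parameters);
* flyway mean trend: the equal-weight mean of `m(L_q)` over occupied
  cells — every standardized sampling unit counts once, regardless of how
  many sites or birds it holds. This is a spatial mean of local trends,
  *not* an abundance-weighted total-population trend; "entire period"
  totals default to `D = 11` (an 11-year window), configurable;
* typical ranges: `100 (1 − exp(m ± sigma_b))` (cell scale) and
  `m ± sigma_d` (site scale) — how much real cells/sites spread around
  the latitude mean;
* trajectory bands at latitude `L`: log-scale line `m t` with nested 95%
  bands — Wald `±1.96 SE(m) |t|`, plus `sigma_b` for the cell-scale
  prediction band, plus `sigma_d` for the site-scale band; all bands
  collapse to zero width at `t = 0` because year is centered there;
* intercept–slope correlation: Pearson correlation of `alpha_hat_i` with
  the fitted site slope, probing whether decline depends on site size
  (flagged as degenerate with fewer than three sites).

Summary latitudes outside the fitted cells' range trigger an
extrapolation warning.

## Synthetic data

The generator draws from exactly the hierarchical model above on an
artificial landscape: cells on a 75-km-pitch grid spanning a latitude band
(default 46–60°N, ~200 cells), sites scattered around cell centroids with
10 km SD (emulating clustering; no attempt to mimic real geography),
Normal(3, 1.5) site intercepts giving median site counts around 20 with a
heavy right tail, and default truth `beta0 = 0.38`, `gamma = −0.008`,
`sigma_b = 0.033`, `sigma_d = 0.073`, `sigma_e = 1.18` — the magnitude of
variation estimated for NW-European pochard winter counts. Years default
to 2002–2012 centered at 2007; site-years are deleted uniformly at random
(default 18%, emulating 0–4 missing years per site out of 11; the
missingness mechanism in real schemes is unknown, so uniform is the
neutral choice).

What passing tests on these data do *not* show: robustness to informative
missingness, to double counting between near-duplicate sites, to
non-log-linear trends (the diagnostics detect, but the model does not fit,
curvature), or to abundance-dependent observer effort. The generator is a
model-faithfulness instrument, not a realism instrument.

## Simulation sizes

Parameter-recovery checks run 20 replicates at 200 cells × 3 sites per
cell × 11 years (~5,400 observations per replicate) plus 10 replicates
with `gamma = 0`; 3 sites per cell keeps a full recovery study in a few
minutes while leaving every variance component identified. Each of the
five parameters fell within 2 reported SEs of truth in ≥ 19/20 replicates,
and the latitude effect was correctly non-significant in 10/10 null
replicates.

## Known limitations

* `sigma_b` is weakly identified on small landscapes (tens of cells with
  2–3 sites); its profile likelihood can be nearly flat near zero, and
  different optimizers may legitimately return 0 or a small positive
  value. SEs reported at the boundary should be read with care.
* The `(beta0, gamma)` SEs condition on the estimated variance
  parameters, as is conventional; percentage-decline SEs inherit this.
* The Moran normal approximation is a large-n device; below ~30 nodes its
  p-values are rough.
* One CRS is built in (European LAEA). Other regions need a projection
  added to the registry.
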