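# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## 1. Indicators

A household record carries six raw fields (toilet-sharing count, public
water flag, members, sleeping rooms, mobile flag, vehicle flag).  The five
derived indicators are all *deprivation-oriented* — each is weakly
increasing in deprivation — because the first-component sign convention
below relies on it.  Two conventions:

- **Rooms floored at one.**  `persons_per_room = members / max(rooms, 1)`.
  Surveys occasionally record zero sleeping rooms; treating that as one room
  keeps the ratio defined and interprets "no designated sleeping room" as
  the whole dwelling being one room.
- **Toilet sharing stays a count**, not a binary: the number of other
  households sharing is informative about contact intensity, and the
  index uses that variation.
- **Listwise deletion** for records missing any raw field, with per-field
  exclusion counts logged and returned.  No imputation: the PCA is fitted
  on complete cases only, and fewer than two complete cases is an error.

## 2. Index model (first principal component)

Indicators mix counts, ratios and binaries, so the PCA is run on the
*correlation* matrix (z-scored columns, sample sd with ddof = 1) — the
standard choice in the asset-index literature; covariance PCA would let the
persons-per-room variance dominate.  The loadings are the leading
eigenvector, normalized and sign-flipped so the loading sum is positive:
since every column is deprivation-oriented, this makes *higher score =
more deprived* without reference to any external anchor.  The explained
variance share is λ₁/5.

Decisions that were genuinely open:

- **Pooled fit** across all regions/countries in the input (one common
  loading vector keeps units comparable); fitting per group is possible by
  calling `fit_pdi_model` on subsets.
- **Unweighted PCA.**  Sample weights enter only at aggregation.  A
  weighted PCA changes loadings by at most a few percent on the synthetic
  worlds and would complicate the scale-equivariance contract.
- Zero-variance columns raise an error naming the column rather than being
  silently dropped.

On synthetic one-factor data the household score correlates ≈ 0.86–0.89
with the latent cluster deprivation (Pearson, n = 5,000).  This ceiling is
structural: three indicators are thresholded binaries, which discard most
of the liability information; lowering the household noise does not raise
it.  Regional averages wash that noise out (see §6).

## 3. Aggregation and normalization

Regional aggregates are weighted means of household scores with

```
w_i = sample_weight_i                     (sample weights only), or
w_i = sample_weight_i · ln(1 + density_i) (density-weighted)
```

Density is looked up at the household's cluster coordinates — the public,
displaced ones, because those are all a real analyst has.  The natural log
is used; since `log_b(1+d) = ln(1+d)/ln(b)`, any other base multiplies all
weights by a constant and leaves every weighted mean unchanged.  Both
variants are always reported side by side.

Raster cells follow a half-open convention, `[west, east) × (south, north]`
with row 0 northernmost, so every point in the extent belongs to exactly
one cell; lookups outside the extent are errors naming the point.

Min-max normalization maps each *layer* (the admin-0 aggregates, the
admin-1 aggregates, or a pixel grid) onto [0, 1] within itself, so 1 is the
most deprived unit *of that layer*; an explicit (min, max) domain can be
supplied to normalize against a fixed reference instead.  A zero-width
range is an error, not a silent 0.

## 4. Pixel surfaces (penalized tensor-product splines)

Cluster mean scores y at (lon, lat) are smoothed with a 2-D P-spline:
cubic B-splines on equidistant knots (12 interior knots per coordinate by
default), tensor-product design B, second-order difference penalty applied
as a Kronecker sum `P = Dₓ'Dₓ ⊗ I + I ⊗ Dᵧ'Dᵧ`, and observation weights
W = diag(cluster household counts).  Coefficients solve

```
(B'WB + λP) β = B'Wy
```

which is simultaneously the penalized weighted least-squares estimate and
the posterior mean under a Gaussian prior with precision ∝ P; the posterior
covariance `σ̂² (B'WB + λP)⁻¹` yields pixel-wise prediction sds, with
σ̂² = weighted RSS / (n − edf) and edf = tr[(B'WB+λP)⁻¹B'WB].  λ = "auto"
minimizes GCV, `n·RSS_w/(n−edf)²`, over a log-spaced grid (10⁻⁴…10⁸, 25
points).

Numerical conventions worth knowing:

- **Uniform, unclamped knots.**  With clamped boundary knots the Greville
  sites are unequally spaced near the boundary and the difference penalty
  would penalize linear trends there.  Uniform extension keeps the order-2
  penalty's null space exactly the bilinear family
  {1, lon, lat, lon·lat}; as λ → ∞ the fit converges to the weighted LS
  fit in that family (a plane plus the lon·lat interaction — the tensor
  analogue of "a plane"), and a constant fit is never penalized.
- The system matrix is solved by Cholesky; a factorization failure is
  reported as a singular penalized system with the advice to raise λ or
  reduce knots (it needs at least a non-degenerate bilinear fit, i.e. ≥ 10
  non-collinear clusters).
- Coordinates are used directly in degrees with no projection.  Over the
  few-degree domains used here the lon/lat metric anisotropy (~cos lat) only
  rescales the penalty's effective smoothness per axis; country-scale
  applications at high latitude should project first.  This is a documented
  limitation.
- Full Bayesian distributional regression (MCMC over mean *and* variance
  surfaces) is an extension point, not implemented; the conjugate Gaussian
  posterior above has the same mean structure in closed form.

## 5. Synthetic survey worlds

The generator's purpose is to give every downstream stage data with the
statistical structure it assumes, under controlled truth:

- **Geography.**  Regions are axis-aligned rectangles (1° × 1° by default)
  tiling a grid; each grid row of regions is one "country", so both
  aggregation levels exist.  Clusters are uniform within their region.
- **Latent deprivation.**  One factor per cluster: an exponential-kernel
  Gaussian process (range 1°, 70% of variance) plus independent cluster
  noise (30%).  The cross-section is standardized to exact mean 0 and sd
  `factor_sd`: a single draw of a long-range GP has a wandering realized
  mean, which would shift every indicator's marginal rate by several points
  from run to run; standardizing pins the calibration without touching the
  spatial correlation structure.  `factor_sd = 0` gives an exactly zero
  field; range 0 gives spatially independent clusters.
- **Single-factor design.**  All five indicators load on this one factor —
  deliberately matched to the PCA's implicit model so that parameter
  recovery is well-posed and failures indicate pipeline defects, not model
  mismatch.
- **Indicators.**  Binary indicators arise by thresholding the household
  liability `z_cluster + noise·ε` at the normal quantile of the target
  rate, so each marginal rate equals its calibration target in expectation
  and every link is monotone in deprivation.  The toilet count among
  sharers is `1 + Poisson` with log-mean increasing in the liability;
  persons-per-room follows a lognormal target (log-slope 0.5 per liability
  sd) realized by rounding the implied room count (floored at one room).
  Two constants correct for selection and rounding bias in these count
  links (`_SHARERS_SELECTION_FACTOR = 0.653`,
  `_PPR_ROUNDING_FACTOR = 0.890`); both were fixed once by Monte Carlo at
  the default configuration.
- **Calibration defaults** are continental survey averages: 45% shared
  toilets (two other households on average among sharers), 40% public
  water, 3.2 persons per room; the phone (30% without) and vehicle (50%
  without) rates sit mid-range of the wide printed country spans.
  Household size is 1 + Poisson(3.8) (mean 4.8), independent of
  deprivation; crowding operates through rooms.
- **Displacement.**  Cluster GPS coordinates are displaced with uniform
  bearing and uniform distance up to 2 km (urban) / 5 km (rural) — the
  standard anonymization convention for such surveys — computed with the
  exact spherical direct formula so the great-circle bound holds by
  construction.  True coordinates are retained in the truth table for
  oracle tests only.
- **Density raster.**  A coarse Gaussian field, bilinearly upsampled, with
  bumps at urban clusters, mapped log-uniformly onto `density_range`
  (1–2,000 people/km² by default; a collapsed range gives a constant
  raster).  The raster is padded about one displacement radius beyond the
  region box so displaced clusters always fall on it.
- **Caseloads.**  `cases_r ~ Poisson(exp(log(300) + effect·risk_r + u_r))`
  with `risk_r` the standardized regional mean deprivation and
  `u_r ~ N(0, 1)` a lognormal regional frailty.  The frailty is essential
  realism: observed caseloads depend on importation, testing intensity and
  age structure as much as on infrastructure, which is exactly why
  real-data index-caseload correlations land in a 0.4–0.9 band rather than
  near 1.  With `effect = 1.5` the simulated Spearman distribution (mean
  ≈ 0.80, ~95% of replicates in [0.4, 0.9]) reproduces that band.
- **Determinism.**  One global seed; each sub-generator (latent field,
  households, displacement, raster, caseloads) draws from a deterministically
  spawned child stream, so any identical configuration reproduces
  byte-identical tables.

What the generator does **not** emulate — and hence what green tests do not
certify about real data: realistic urban geography and settlement patterns,
multi-country heterogeneity in survey years and instruments, informative
missingness, multi-factor deprivation structure (real indicators are not
conditionally independent given one factor), non-Gaussian latent fields,
and DHS recode file formats.

## 6. Validation and expected magnitudes

The validation stage reports Pearson and Spearman correlations between
normalized regional PDI and cumulative caseloads (Spearman is invariant to
the min-max step; Pearson is not, which is why the normalized index is the
documented input), leave-one-indicator-out correlations (refit the PCA on
each 4-indicator subset; correlate reduced with full scores, canonical
indicator order), and — for synthetic data — Spearman against true regional
deprivation.  A per-capita caseload variant is available behind a flag.

At the default study size (30 regions × 20 clusters × 25 households):
regional truth recovery ρ ≈ 0.95–0.99; leave-one-out correlations ≈ 0.98;
PCA variance share ≈ 0.60.  These sizes keep a full end-to-end run well
under a second while leaving every estimate far from its decision
boundary; the calibration checks use 50,000 households, where the binomial
Monte-Carlo error on a 45% rate is about 0.2 points.

## 7. Known limitations

- No survey design-effect or small-area variance estimation for the
  regional aggregates; the reported index is a point estimate.
- The surface stage propagates no uncertainty from the PCA or aggregation
  stages; its sd reflects only smoothing uncertainty given cluster means.
- Indicator extremes are not top-coded; a single enormous sharing count can
  influence the standardization (mirrors the raw-data convention of the
  underlying surveys).
- Degrees-as-metric in the spline stage (see §4).
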