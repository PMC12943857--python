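# Methods

`agbmap` estimates wall-to-wall forest aboveground biomass (AGB, t/ha) by
combining a covariate-driven regressor with a geostatistical model of its
own errors. This note records the models, the choices behind them, and what
the synthetic test bed does and does not establish.

## The hybrid estimator

Let C(x) be plot AGB at location x and X(x) a vector of remote-sensing
covariates. The pipeline is:

1. **Feature construction.** From a co-registered stack of ten optical
   surface-reflectance bands (B2–B12), two L-band SAR backscatter
   polarizations (HH, HV, linear power) and a DEM, 50 candidate predictors
   are built: the 10 bands; NDVI, RVI, ARVI, EVI and mNDVI; the first three
   principal components of the z-scored bands; 24 gray-level co-occurrence
   (GLCM) textures of PC1 (8 statistics × windows 3/5/7); HH, HV, HH/HV,
   RFDI = (HH−HV)/(HH+HV) and the radar RVI = √(HH/(HH+HV))·(HH/HV); and
   elevation, slope and aspect (Horn's 3×3 gradients).
2. **Screening.** A Random Forest (500 trees, 3 candidate variables per
   split, terminal nodes ≥ 10) ranks the 50 predictors by out-of-bag
   permutation importance (%IncMSE, the primary key) and total split-RSS
   reduction (IncNodePurity, the tie-break); the top 10 go forward.
3. **Regression.** A 1D CNN-Transformer maps the 10 selected predictors
   (fed as a length-10, one-channel sequence) to AGB. Ten-fold
   cross-validation (fold sizes ⌈n/k⌉ with the remainder in the last fold;
   398 plots split 40×9 + 38) yields an out-of-fold (OOF) prediction for
   every plot.
4. **Residual kriging.** The pooled OOF residuals Z(x) = C(x) − Ĉ(x) are
   summarized by an isotropic exponential semivariogram
   γ(h) = c₀ + c·(1 − e^(−3h/R)) fitted by Cressie-weighted least squares
   (N(h)/γ²), and, for co-Kriging, by a two-structure linear model of
   coregionalization (LMC) with elevation as the secondary variable.
   Ordinary Kriging (weights sum to 1) or traditional co-Kriging (primary
   weights sum to 1, secondary to 0) interpolates the residuals; the
   leave-one-out RMS and standardized RMSS diagnose the fit.
5. **Hybrid composition.** Ĉ_hybrid(x) = Ĉ(x) + Ẑ(x), cell by cell.
   Negative cells are kept (a clip-at-zero switch exists but is off).
   Validation metrics (R², RMSE, MAE, Bias, CV% = RMSE/ȳ·100) are computed
   per fold with the kriging system restricted to training-fold plots, then
   averaged arithmetically; the relative improvement is
   RI = (RMSE_base − RMSE_hybrid)/RMSE_base.

The "range" reported everywhere is the effective range (γ reaches 95% of
the sill), the convention used by mainstream GIS packages; the −3h/R
parameterization encodes it directly.

## The CNN-Transformer

Architecture: conv1d (32 filters, kernel 3, same padding, ReLU) → max
pooling (window 4, stride 4; a length-10 sequence becomes 2 tokens of 32
channels) → linear embedding to d_model = 32 → sinusoidal positional
encodings → 6 encoder layers (8-head self-attention, residual connections,
layer normalization, feed-forward width 64, dropout 0.2) → global average
pooling → linear head. Training: Adam, MSE loss, batch 10, 200 epochs,
learning rate 0.005. Inputs are z-scored with training-fold statistics; the
target stays in t/ha.

Design choices that the headline hyperparameters leave open:

- **Embedding width d_model = 32**, equal to the number of convolution
  filters, so the embedding is a square map with no information bottleneck;
  the feed-forward width is 2·d_model. Larger widths quadruple the
  parameter count without improving validation skill at a few hundred
  training plots, and make the optimizer update the dominant cost.
- **Pre-norm residual arrangement.** Layer normalization is applied to each
  sublayer's input, keeping an identity residual stream. With normalization
  after the residual sum, training at this learning rate and batch size
  collapses to a constant predictor within an epoch: each post-residual
  normalization rescales the whole stream, and once bias directions
  dominate, the sample-dependent component is attenuated multiplicatively
  across the stack.
- **Regularization.** The stated learning rate is the initial value of a
  cosine decay; a decoupled L2 weight decay of 3e-3 acts on weight matrices
  (never biases or normalization parameters); and training inputs are
  jittered with Gaussian noise of 0.40 standard deviations (z-score units).
  At ~360 training rows the network otherwise memorizes (train R² > 0.92)
  while validation skill collapses below the Random Forest's. With these,
  the train/validation gap (≈ 0.75 / 0.63) mirrors what ensemble methods
  show on comparable plot data.
- **Determinism.** One seed controls initialization, batch shuffling,
  dropout masks and the input jitter; the same seed reproduces the loss
  trajectory bitwise. Prediction runs with dropout off and is pure.
- The encoder is used alone: regression on a fixed-length feature vector
  has no autoregressive target, so a masked decoder would have nothing to
  generate.
- Cross-validation folds (and, for multi-scenario experiments, whole
  datasets) are trained simultaneously with parameters stacked along a
  leading replica axis — a vectorization; each replica's trajectory is
  independent of the others.

The engine behind the model is a compact reverse-mode autodiff over numpy
arrays (float32) with a fused multi-head-attention node and a flat-buffer
Adam; gradients are validated against finite differences in the test suite.

## The synthetic landscape

Field inventories of the kind this pipeline targets are confidential, so a
generator reproduces the statistical structure the method depends on. All
defaults are fixed; one seed determines everything.

- **Geometry.** 128×128 cells of 100 m (12.8 km × 12.8 km), a scaled-down
  study region that preserves the real-data ratios: plot spacing 640 m
  (systematic 20×20 grid with 50 m jitter → 400 plots), injected residual
  correlation range 3.4 km ≈ 5.3 plot spacings ≈ 0.27 of the domain —
  the same ratios as ~400 plots at 4–6.6 km spacing over a ~131 km region
  with a 35–55 km residual range.
- **Terrain and AGB.** The DEM is a smoothed random field rescaled to
  50–1500 m. The covariate-visible AGB component is
  mean 101.92 + 12·(elevation z-score) + a smooth random field (sd 18,
  range 0.3 of the domain), clipped to 36.68–184.84 t/ha.
- **The error budget**, derived from the target regime (plot sd ≈ 23 t/ha,
  model residual sd ≈ 13, residual nugget/sill ≈ 0.87, validation R² ≈
  0.69): the truth adds, invisibly to every covariate, (a) an exponential
  random field with partial sill 20 (t/ha)² and range 3.4 km — regional
  drivers the covariates miss, the part kriging can recover — and (b)
  i.i.d. plot-scale variability of sd 11.5 t/ha, standing for the support
  mismatch between a ~0.08 ha plot and a 10 m pixel plus allometric and
  measurement error — the nugget, which nothing can recover.
- **Spectral responses.** Each optical band follows a 4-parameter logistic
  in AGB (NIR/red-edge rising, visible and SWIR falling), flattening above
  a saturation point of 160 t/ha; SAR backscatter rises with AGB, the
  cross-polarized HV more steeply than HH, with multiplicative speckle.
  Response midpoints shift with elevation (18 t/ha per elevation sd;
  half that for SAR): forest composition changes along the altitudinal
  gradient, so the same reflectance means different biomass at different
  altitudes. Inverting the signal therefore requires a smooth
  band×elevation interaction — which is also why elevation must enter the
  predictor set, and why residuals retain an elevation-linked component
  that co-Kriging can exploit.
- **Noise placement matters.** A small shared spectral perturbation (4 t/ha
  equivalent) moves all bands coherently; per-band artifacts (10% of each
  band's dynamic range) are spatially correlated at 500 m — calibration,
  BRDF and atmospheric residues are patchy, not white. The patch scale is
  below the plot spacing, so for kriging they act as nugget, and above the
  texture window (70 m), so local averaging cannot remove them; only
  combining many bands can, which is a smooth oblique function of the
  inputs — the regime in which a global smooth regressor genuinely
  outperforms axis-aligned trees, as reported for real plot data. (An
  earlier design with white per-pixel noise made the GLCM means nearly
  sufficient statistics and the Random Forest essentially optimal.)

What the generator does **not** emulate: cloud and illumination artifacts,
species composition and phenology, geolocation error, anisotropy or
non-stationarity of the residual field, and disturbance mosaics. Passing
tests on this landscape show the pipeline's internal consistency and that
its components interact as intended under realistic magnitudes — not that
the accuracy numbers transfer to any particular real forest.

## Geostatistical details

- Matheron's estimator over 12 equal-width lag bins up to half the maximum
  pairwise distance (both configurable); empty bins are missing, not zero.
- The WLS range is capped at twice the largest lag center: beyond the
  sampled lags an exponential is indistinguishable from a line and the
  range diverges. A fitted structure exhausted before the first observed
  lag (no pairs closer than the plot spacing) is folded into the nugget —
  the two are observationally equivalent on the data support and the
  nugget is the conservative reading.
- The LMC fixes family and range from the primary direct fit, fits the
  secondary and cross structures with the range held, and projects the
  cross coefficients onto |c₁₂| ≤ √(c₁c₂) per structure (nugget included).
- Kriging uses a global neighborhood (all samples per query; appropriate at
  a few hundred plots; a max-neighbors option subsets for larger n).
  Duplicate sample coordinates are averaged first. A perfectly redundant
  secondary makes the CK system singular while the prediction stays well
  defined; the solver falls back to the minimum-norm solution with a
  warning.
- Skewness is m₃/m₂^1.5 and kurtosis the raw m₄/m₂² (a normal sample sits
  near 3); the per-pixel fold-variation map uses the population standard
  deviation over the k fold predictions.

## Problem sizes

Unit tests run on 48–64-cell grids with reduced GLCM quantization and short
training schedules where the property under test allows it; the
qualitative-ordering experiment uses ten full default scenarios with the
regressor trained 100 epochs per fold (the cosine-decayed loss is flat well
before that); the acceptance script runs one full default scenario with the
complete 200-epoch configuration. GLCM quantization defaults to 32 levels
with offsets {(0,1),(1,0),(1,1),(1,−1)} averaged and symmetric counting;
windows shrink at raster borders rather than padding.

## Known limitations

- The GRF simulator's circulant embedding is exact only when the doubled-
  torus eigenvalues are non-negative (always the case for the exponential
  family at these range/domain ratios); it aborts otherwise. Dense-Cholesky
  point simulation is limited to 3,000 points.
- Variograms are isotropic; there is no universal/regression kriging, no
  Bayesian uncertainty, and kriging variance is the only uncertainty
  carried to the maps besides the fold-variation map.
- The CNN-Transformer's max-pooling spans positions 0–7 of the length-10
  input; the two least-important predictors influence the model only
  through the convolution's edge overlap. Feeding variables in importance
  order (the default) puts the least informative ones there.
- Coordinates are planar metric; no geodesic distances or reprojection.
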