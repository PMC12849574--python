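# Methods

This note documents the models, conventions and design choices behind
`swarmkin`, in the order the pipeline applies them.

## Data model and units

A track is an ordered sequence of (t, X, Y, Z) detections for one
individual. Positions are stored in centimetres in a world frame with
the swarm marker at the origin (X normal to the sunset horizon, Y
vertically up, Z parallel to the horizon); speeds are in m/s. Unit
conversion happens only at I/O, and the camera-to-world rigid transform
is a user input (a rotation with det +1 and a translation), since
device mounting geometry varies between deployments.

## Filtering

Four sequential filters isolate swarming tracks, each evaluated on the
frames surviving the previous stages:

| stage    | rule                                   | convention |
|----------|----------------------------------------|------------|
| temporal | start ≤ t ≤ end (default 12–32 min after sunset anchor) | closed window |
| spatial  | X and Z within ±100 cm                 | closed interval; Y unconstrained |
| speed    | mean speed ≥ 0.50 m/s                  | inclusive threshold |
| duration | flight time > 25 s                     | strict inequality |

Mean speed uses the device speed series (trapezoid time-weighting) when
present, otherwise chord-length finite differences at the native frame
rate with no smoothing: at 100 fps the chord bias is a fraction of a
percent, far below the 0.50 m/s threshold. Flight time defaults to the
summed inter-frame time of retained frames (gaps longer than 1.5× the
median frame interval do not count); the last-minus-first span is
available via `duration_mode="span"`. The per-minute activity series
divides detection counts by frames per minute (6000 at 100 fps), so a
mosquito airborne through a whole minute contributes exactly 1.0.

## Swarm structure

The swarm is a single 3D Gaussian fitted to all frame positions of a
replicate's swarming tracks: the one-component Gaussian-mixture optimum
is the sample mean and maximum-likelihood covariance (divisor n), so it
is computed in closed form; a diagonal jitter of 1e-9·trace/3 guards
near-singular scatters, and fewer than 4 points or a rank-deficient
scatter raise a degenerate-swarm error. The confidence ellipsoid scales
the covariance eigenvalues by the chi-squared(df=3) quantile at the
confidence level (default 0.90, critical value ≈ 6.2514); points are
core when their squared Mahalanobis distance does not exceed it.

Volume convention: the phrase "product of the principal axes" admits
three readings, so the volume is configurable — the geometric ellipsoid
volume (4/3)π·r₁r₂r₃ (default, dimensionally a volume and the one used
throughout), the full-axes product 8·r₁r₂r₃, and the bare semi-axes
product. All scale identically (∝ det(Σ)^(1/2)), so trend *shapes* are
convention-independent.

A track is core when ≥ 50% of its frames are core
(`track_core_fraction`, default 0.5): the source definition ("tracks
within the ellipsoid") names no fraction, and a majority rule is the
natural middle ground between any-frame and all-frames readings.
Density is core tracks / ellipsoid volume per replicate; group
aggregation averages per-replicate densities rather than dividing mean
counts by mean volumes (the two differ under replicate heterogeneity).

## Trend models

- **Quadratic volume law.** V(x) = ax² + bx + c on the OSR codes
  {0, 50, 100, 150, 200} by ordinary least squares — the model is
  linear in its coefficients, so the nonlinear least-squares optimum
  coincides with the normal-equations solution.
- **Smoothing spline.** Penalized cubic B-splines with interior knots
  at the interior data sites and the exact second-derivative Gram
  penalty (two-point Gauss–Legendre per knot span, exact for cubic
  bases). The smoothing weight is chosen by generalized
  cross-validation over a log grid, excluding the degenerate
  interpolating limit (edf > 0.9 n), unless a fixed λ is given. The
  effective degrees of freedom is the trace of the smoother matrix; for
  a shared λ the fit matches scipy's natural cubic smoothing spline to
  machine precision (cross-checked in tests).
- **Mixed model.** speed = β₀ + β₁·density + b_replicate + ε via
  statsmodels MixedLM (Gaussian, identity link, ML). Pseudo-R² is the
  Nakagawa *marginal* form: var(fixed predictions) over var(fixed) +
  var(random intercept) + residual variance. A single replicate falls
  back to OLS with a logged warning. In the pipeline, replicate ids of
  the form `<group>_<cohort>` share a random intercept per cohort
  (mirroring independent rearing cohorts); other id shapes group by the
  full id.
- **AIC comparison.** AIC = 2k − 2·logL with the Gaussian log-likelihood
  at the ML residual variance; k counts mean parameters plus one for
  the variance (spline: edf + 1). Candidates whose k reaches the sample
  size are skipped and flagged, as is a non-converging 4-parameter
  logistic y = d + (a−d)/(1+(x/c)^b); ties keep candidate order.
  Because AIC depends on the raw data, published AIC values are not
  reproduction targets — model *ordering* on synthetic data is.

## Classifier

RandomForestClassifier with 30 trees (other hyperparameters at
ecosystem defaults), OSR codes treated as categorical labels,
stratified 80/20 split at frame granularity by default. Frame-level
splits place frames of one track on both sides and therefore inflate
accuracy; `split_unit="track"` gives the leakage-free variant and both
are reported in the docs deliberately. SMOTE is implemented in-package
(interpolation between a minority sample and one of its k=5 nearest
same-class neighbours, classes equalized to the majority count,
reduced k or duplication fallbacks for tiny classes) and touches the
training split only — `run_classifier` asserts the test partition's
checksum is unchanged. ROC-AUC uses mean class probability across
trees; importances are mean decrease in impurity normalised to sum
to 1. A practical cap (`max_rows`, default 50 000) subsamples the
feature table with the run seed before splitting, since hour-long
recordings at 100 fps yield millions of frames with heavy within-track
redundancy.

## Synthetic recordings

The generator emulates the statistical structure the analysis assumes,
not mosquito aerodynamics:

- **Motion.** Each swarming track is a smooth circular loop (radius
  r with r² = 1.5·λ_min of the scenario covariance) around a centre
  drawn from N(μ, Σ − (r²/3)I); loop orientation is uniform, so pooled
  positional covariance converges to Σ. The loop rate is set so the
  realized chord-speed equals the per-track target speed (drawn
  N(speed_mean, speed_sd), floored at 0.55 m/s) to well under 2%.
- **Defaults as study conditions.** Group speeds (0.73/0.68/0.66/0.79/
  0.87 m/s), speed SDs, track counts (20/26/27/12/15) and ellipsoid
  volumes (399.8/302.1/327.4/553.3/625.3 cm³) default to the published
  per-group means; replicate volumes get multiplicative lognormal noise
  (sd 0.3, matching the observed ~50% coefficients of variation).
  Swarm shape is a fixed unit-determinant diagonal (1.6, 0.7, 1.0)
  scaled to the target volume; swarming durations default to 35–60 s.
- **Noise tracks** violate exactly one filter each: slow (< 0.50 m/s),
  short (< 25 s) or entirely outside the ±100 cm X box. The generator
  can assert the constructive guarantee by running the filter chain.
- **Exact-moment mode** (`empirical_moments`): the pooled swarming-frame
  mean and covariance are affinely matched to the scenario values
  (the same idea as sampling "without noise" via moment-matched
  multivariate normals), then each track's time axis is rescaled to
  restore its mean speed, clipped so flight time stays above 26 s and
  speed above 0.52 m/s — retiming does not move positions, so the
  matched moments survive. With this mode and zero replicate noise,
  end-to-end recovery of a generating volume law is exact to rounding,
  which is what a "noise-free" recovery experiment should mean for an
  estimator chain whose only other error source is sampling
  variability.
- **Not emulated:** male–female chasing and coupling, wind and light
  forcing, device dropouts and identity switches, non-Gaussian swarm
  shapes. Passing recovery tests therefore certifies the estimator
  chain, not robustness to those real-data features.

All randomness flows through a single seeded NumPy PCG64 generator;
fixed seeds reproduce byte-identical files.

## Problem sizes

Containment calibration uses 10⁵ Gaussian draws (tolerance ±1%), volume
recovery 10⁴ draws (< 5%). End-to-end trend recovery runs 5 groups × 3
replicates × 10 tracks of 35–42 s; classifier properties use 5 × 500
five-feature rows. The default synthetic study (published counts and
durations) produces ~1.3 M frames and runs the full pipeline in well
under a minute on one core.

## Known limitations

- The Gaussian swarm model understates volume for strongly
  non-ellipsoidal aggregations by construction.
- det(Σ̂)^(1/2) has a small negative bias at few effective samples
  (~5% at 60 tracks), visible as replicate scatter in volume estimates.
- The frame-level classifier split is optimistic; use track-level
  splits for honest generalization estimates.
- GLMM coefficients, spline AICs and per-class accuracies published for
  the original recordings depend on raw replicate-level data and are
  validated here by parameter-recovery properties instead.
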