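# Methods

## Stimulus model and conventions

Scaled gratings are defined in polar visual-field coordinates by
`I(r, θ) = cos(ω_r ln r + ω_a θ + φ)`, with `ω_a` (cycles/revolution)
constrained to integers to avoid edge artifacts and `ω_r` in radians per unit
of `ln r`. The NSD-style catalog has 28 classes — 6 pinwheels (`ω_r = 0`),
6 annuli (`ω_a = 0`), 6 forward spirals (`ω_r = −ω_a = k`), 6 reverse spirals
(`ω_r = ω_a = k`) and 4 mixtures — each with 4 phases (0, 1.57, 3.14, 4.71).
Because spiral magnitudes are integers near `k√2`, base frequencies
`√(ω_r²+ω_a²)` match across shapes only approximately (worst case ~10%, at
base 11 vs 7√2); the extreme base frequencies in the catalog are the spirals
at 4√2 ≈ 5.66 and 91√2 ≈ 128.7.

Conventions fixed once for the whole package:

* θ counterclockwise from the positive x-axis, y up in visual-field
  coordinates.
* The phase-gradient magnitude `√(ω_r²+ω_a²)/r` is radians/degree; local
  spatial frequency in cycles/degree divides it by 2π. This convention is not
  assumed — a finite-difference phase-gradient oracle on rendered images
  verifies it in the test suite before any model code relies on it.
* Local orientation is the phase-gradient direction
  `θ + atan2(ω_a, ω_r)` reduced mod π. Under this convention an annulus on
  the right horizontal meridian has orientation 0 and vertical contours, so
  `cos 2θ_l = +1` selects "vertical" and a positive `p₁` means vertical >
  horizontal. Forward spirals carry `(ω_r, ω_a) = (+k, −k)`; the sign choice
  is immaterial to the model because orientation enters only through
  `cos 2θ` and `cos 4θ`.
* The anti-aliasing mask radius is where the local frequency reaches a cutoff
  (`√(ω_r²+ω_a²)/(2π·cutoff)`); the renderer defaults the cutoff to the pixel
  grid's Nyquist frequency, so the `ln r` singularity and all aliased pixels
  are always inside the mask (set to 0, mean luminance). Reproducing a
  specific display's literal mask radii would require its pixel density,
  which is a non-goal.

## Tuning model

Responses are modeled over spatial **period** (deg/cycle) rather than
frequency because period grows roughly linearly with eccentricity. The 1D
per-bin curve is `A·exp(−(log₂p_l − log₂p_b)²/(2σ_b²))`: gain `A` (% signal),
preferred period `p_b` (deg/cycle) and bandwidth `σ_b` (octaves, log base 2
throughout; FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ).

The 2D map model shares one σ across the map and constrains preferred period
to be affine in eccentricity, modulated by absolute orientation (`p₁`, `p₂`)
and by orientation relative to the vertex's polar angle (`p₃`, `p₄`);
amplitude varies with absolute orientation only (`A₁`, `A₂`) — allowing
relative-orientation amplitude terms is deliberately out of scope. The
printed form of the preferred-period equation contains a typo (`p_v` on both
sides); the base term is implemented as `a·r_v + b`, the reading consistent
with the statement that preferred period varies linearly with vertex
eccentricity.

The parameter container enforces `|p₁|+|p₂|+|p₃|+|p₄| < 1` and
`|A₁|+|A₂| < 1`, guaranteeing positive periods and gains everywhere. Fitted
values in practice are below 0.2 in magnitude, far inside the bounds.

## Fitting

**Loss.** Per vertex, the L2-normalized MSE between the 28-class mean-beta
vector and the model prediction, weighted by `1/σ_v²`, then averaged across
vertices (averaging vs summing is equivalent up to learning-rate scaling; the
average makes the loss magnitude independent of map size). `σ_v²` is the
sample variance (n−1 denominator) across repeated trials, computed per class
and averaged over classes — all 28 classes for the 2D loss, the 24 primary
classes for the 1D pathway; both class sets are explicit arguments. Ragged
trial counts (e.g. trials dropped as consecutive repeats upstream) are
NaN-padded; every used class needs ≥ 2 trials.

Zero-variance vertices (exactly noiseless synthetic data) would receive
infinite weight; if *all* variances are zero the weighting is vacuous and
unit weights are used, otherwise zero variances are floored at the smallest
positive variance.

**Optimizer.** The 9-dimensional problem is smooth, so `fit_2d_model` uses
L-BFGS-B (scipy) with finite-difference gradients and box bounds
(σ ∈ [0.05, 10], a ∈ [0, 2], b ∈ [0.01, 5], |p_i| ≤ 0.24, |A_i| ≤ 0.49 —
the per-parameter boxes imply the positivity constraints above). Defaults:
ftol 1e−14, gtol 1e−10, ≤ 5000 iterations; initialization σ=2, a=0.1, b=0.3,
orientation terms 0, near typical fitted values and inside the constraint
region. Fits are deterministic given (data, init, config); typical
convergence is ~20–40 iterations (≈0.6 s for 1000 vertices × 28 classes on
one CPU). On noiseless forward-model data the generating parameters are
recovered to ~1e−6.

**1D pathway.** Vertices are binned by pRF eccentricity (default 0.5°–4.0° in
0.5° steps; half-open [left, right) bins, last bin closed). Within a bin,
betas are averaged over trials, vertices, and the four primary shapes at each
base-frequency level (levels matched by rank; mixtures excluded); the local
period of a level is assigned at the bin-center eccentricity using the mean
base frequency of the collapsed shapes. Per-bin curves are fit by bounded
nonlinear least squares (`curve_fit`), and an OLS line summarizes preferred
period vs eccentricity.

*Binning bias.* Because vertices within a bin span a range of eccentricities,
the binned curve peaks at `r_c · geomean_e[(a·e+b)/e]` rather than exactly
`a·r_c + b`. With foveally dense (log-uniform) layouts this inflates the most
foveal bin's apparent preferred period by ~5%; it is a property of binning,
not of the fitter, and is negligible beyond ~1° with 0.5° bins.

## Aggregation

Subjects are combined by inverse-variance weighting with a single precision
per subject (`σ_s²` = mean vertex variance over the fitted map, using the
class set of the corresponding pathway), applied identically to every
eccentricity bin and every model parameter. CIs are percentile bootstrap
(default 10,000 resamples, 16th–84th percentiles) resampling subjects'
parameter values together with their weights — resampling values, not
refitting. Within-subject ROI contrasts difference each subject's two ROI
estimates and weight by the mean of the two ROI precisions.

With 8 subjects, the percentile bootstrap is known to undercover slightly
(true coverage of a nominal 68% interval is ≈60–65%); the calibration test
therefore pools coverage across the 9 parameters over 20 simulated cohorts,
where a per-parameter estimate from 20 cohorts would be dominated by binomial
noise (SD ≈ 10 points).

## Synthetic data

The generator emulates the structure the analysis assumes, with defaults set
to the NSD-like study conditions: 8 subjects, 1000 V1 vertices over 0.5–4.2°
eccentricity (a 1–12° variant emulates the wide-aperture design), 28 classes
× 8 trials, noiseless betas from the 2D model at each vertex's pRF center,
and independent Gaussian trial noise. The per-vertex noise SD is
`0.5 × mean response` scaled by a unit-mean lognormal multiplier (log-SD 0.3)
so that vertex and subject precisions differ meaningfully; 2% of vertices get
sign-flipped gain to exercise the negative-mean exclusion; pRF size is
`0.1 + 0.2·ecc` (loosely following published V1–V3 size-vs-eccentricity
trends; only the filtering rule consumes it). Eccentricities are log-uniform
(denser foveally, a coarse stand-in for cortical magnification), polar angles
uniform. Canonical generating parameter sets for V1/V2/V3 and the
wide-aperture V1 variant ship as constants.

What the generator does **not** emulate: GLM-derived noise structure
(temporal autocorrelation, run effects), spatial correlation of noise across
the cortical surface, pRF estimation error, and systematic deviations from
the 2D model's functional form. Passing recovery and calibration tests
therefore validates the estimation machinery under the model's own
assumptions, not robustness to model mismatch in real data.

Reproducibility: each subject regenerates bit-identically from
(config, subject index); cohort runs are bit-reproducible from the RunConfig;
CSV interchange uses 17-significant-digit floats with round-trip parsing so
written betas reread exactly.

## Filtering

Three rules, applied in order with each exclusion charged to the first
matching rule: negative mean response (over 24 primary classes for the 1D
pathway, all 28 for 2D), pRF center inside the largest anti-aliasing mask
(default 0.5°), and — 2D only — pRF center more than one pRF size outside the
stimulus extent (default 4.2°). Boundary equalities keep the vertex.

## Problem sizes

Tests run single-subject fits at 1000 vertices, cohort recovery at 8×1000,
and calibration at 20 cohorts × 8 subjects × 1000 vertices (~2.5 min); the
acceptance script re-runs the 8-subject cohort in a few seconds. These sizes
match the emulated study conditions; recovery precision scales as expected
with vertex count.

## Known limitations

* The fitter assumes one shared bandwidth per map; maps with strong
  eccentricity-dependent bandwidth will be summarized by a compromise σ.
* Between-subject parameter jitter is optional and off by default, so default
  cohorts test measurement noise only, not population heterogeneity.
* The bootstrap resamples fitted values; uncertainty from the fit itself
  (conditional on a subject's data) is not propagated.
* Real-data ingestion is via the documented CSV schema; native neuroimaging
  surface formats are out of scope.
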