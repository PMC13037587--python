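# Methods

This document describes the models, estimators, parameter defaults and
numerical choices behind each module, and the limitations that follow
from them. Quantitative claims about performance are restricted to what
the test suite (`tests/`) and the target script
(`scripts/acceptance.py`) actually compute.

## Synthetic data generator (`simgen`)

The generator exists so that every estimator in the package can be
validated against known ground truth. Its scope is deliberately narrow:
it produces ROI-averaged line-scan *time series* (one value per scanned
line), not full space×time rasters, because every downstream routine
consumes ROI-averaged traces. Spatial structure appears only as a
per-trace line extent (µm) used to scale signal masses, and in the 2-D
puncta image generator.

### Transient kernel

One event in ΔF/F₀ units: a linear rise from 0 to the amplitude over
`time_to_peak_ms`, then a two-phase exponential decay. The first rate is
fixed by requiring 50% of the amplitude to remain at `decay_t_half_ms`
after the peak; the second rate is fixed by requiring 5% to remain at
`duration_ms`. When no duration is given it defaults to the natural
endpoint of a single-rate decay, `ttp + log2(20) * t_half` (the time at
which a pure exponential with that half-life reaches 5%), making the
default kernel a single-rate decay truncated at 5%. The 5% floor
(`KERNEL_TAIL_FRACTION`) exists because an exponential never reaches
zero; it also defines the "duration" endpoint used by the kinetics
module, keeping generator and estimator conventions identical.

Polarity −1 mirrors the kernel for Mode 2 dips (net ATP consumption);
all analysis formulas operate on polarity-folded deviations so both
modes share one code path.

### Beat train and channels

Events are placed at a fixed pacing frequency (default 3.5 Hz) with
Gaussian timing jitter (default SD 5 ms), a fixed Ca²⁺→ATP lag (default
20 ms), and optional log-normal per-event amplitude dispersion
(`amplitude_cv`). Three channels are emitted: a Ca²⁺ indicator, the ATP
sensor, and an ATP-insensitive reference that carries no signal — only
artifacts and noise.

### Artifacts

Two multiplicative common-mode contaminations, applied identically to
sensor and reference before additive per-channel Gaussian noise:

- a slow sinusoid (`common_mode_amplitude`, default frequency 0.8 Hz)
  standing in for focus drift and slow motion;
- a defocus z-step: a square depression of the collection efficiency
  (20% per 5 µm of nominal depth) over a configured interval, standing
  in for an axial displacement test.

Because the contamination is multiplicative and identical in both
channels, the ratio R/R₀ cancels it exactly up to noise — which is what
the artifact-control module is designed to demonstrate.

## Preprocessing (`preprocess`)

F/F₀ normalization divides each channel by a baseline estimated from
event-free samples. Two estimators are provided:

- **percentile** (pipeline default, 10th percentile): robust when events
  occupy a minority of samples and all deflections are positive;
- **density mode**: the center of the densest value cluster (half-sample
  mode), preferred when Mode 2 dips make low percentiles biased, or when
  events of both polarities are present.

Ratiometric correction is the pointwise quotient of sensor F/F₀ by
reference F/F₀. The quotient's own baseline can differ from 1 — the two
channel baselines may be estimated at different phases of a common-mode
oscillation — so the pipeline renormalizes the ratio (`normalize_f0`
applied to the quotient) before event detection.

A rolling-percentile baseline (`rolling_f0`) handles slow drift that a
global baseline cannot.

## Event detection (`events`)

Detection operates on the normalized (or ratio-corrected) trace:

1. boxcar smoothing (9 samples ≈ 18 ms at 2 ms sampling — wide enough
   to suppress single-sample noise, narrow relative to the ≈68 ms rise);
2. noise SD estimated from the median absolute deviation of first
   differences divided by √2 (insensitive to the events themselves);
3. baseline re-centering by density mode with iterative refinement on
   sub-threshold samples;
4. candidate runs where the smoothed deviation exceeds `k_sigma` (2.0)
   times the noise for at least `min_sustained` (3) samples, confirmed
   only if the run peaks above `confirm_sigma` (3.5); the two-threshold
   scheme keeps single-noise-sample crossings out while still anchoring
   event boundaries at a low threshold;
5. boundary extension down to 0.25× the threshold toward baseline, then
   a merge of overlapping same-polarity spans so no two events of one
   polarity overlap.

Event filters: minimum mean F/F₀ of 1.025 over the event (2.5% sustained
deviation) and minimum spatial extent of 5 µm (when extents are
available) separate real transients from noise flickers; Ca/ATP pairing
greedily matches events within 50 ms of onset lag.

Detection quality is a tested property, not an assumption: the
acceptance suite requires mean recall and precision ≥ 0.95 over 50
seeded traces at 5% noise CV.

## Kinetics (`kinetics`)

Per event, on the polarity-folded deviation:

- **onset**: the interpolated 5%-of-amplitude crossing on the rising
  limb, extrapolated to baseline assuming a linear rise (exact for the
  kernel, insensitive to where the detector placed the onset);
- **time to peak**: peak time minus onset;
- **decay t₁/₂**: forward-interpolated crossing of 50% of the peak
  amplitude after the peak;
- **duration**: onset to the 5% return (the same tail fraction the
  generator uses);
- **signal mass**: trapezoidal integral of ΔF/F₀ over the event, ×dt
  (ms) and × line extent (µm) when available; polarity-signed.

Two frequency conventions are reported: event count per record time,
and the reciprocal mean inter-onset interval. `max_sustainable_frequency`
is the reciprocal of a full event duration — the pacing rate above which
the next beat would land inside the recovery window.

**Noise sensitivity and beat averaging.** On a single noisy event the
amplitude is read at the raw sample maximum (biased upward by the
largest noise excursion) and t₁/₂ at the first crossing (biased early);
both biases shorten the apparent decay. `beat_average` therefore aligns
all events of a trace on the peak of a lightly smoothed copy (boxcar 5)
and averages the raw deviations sample-by-sample; `averaged_kinetics`
computes kinetics on that mean transient. The noiseless average is
exact, and the tests require the averaged t₁/₂ at 1% channel noise to
fall within 15% of truth while the single-event mean lies farther away.
Single-event records remain the right input for signal-mass statistics
(integration averages noise) and event counts.

## Calibration (`calibrate`)

Single-site binding sensor: F/Fmax = (ATP + Kd/Rf)/(ATP + Kd), inverted
exactly as ATP = Kd·(F/Fmax − 1/Rf)/(1 − F/Fmax). Defaults Kd = 1460 µM,
Rf = 3.8 describe the cytosolic ATP sensor; they are sensor constants,
not fit parameters, and were determined in a different cell type than
the nodal tissue they are applied to — the pipeline records this
assumption in its calibration output.

`estimate_fmax` reads Fmax from a saturating-perfusion plateau and can
correct for incomplete saturation: at 10 mM perfusate the sensor sits at
fraction (1/Rf) + (1 − 1/Rf)·C/(C + Kd) ≈ 0.906 of true Fmax, and
dividing the plateau by that fraction recovers the asymptote. The
inversion raises on F ≥ Fmax (the equation diverges), clips
sub-zero-ATP fluorescence to 0 µM with a warning by default, and raises
in strict mode.

## Coupling fits (`coupling`)

Per-cell transfer functions on (Ca mass, ATP mass) event pairs:

- **two-line mixture**: EM over K ∈ {1, 2} lines through a shared
  intercept structure, selected by BIC; slopes, responsibilities and a
  majority-vote per-cell gain label are reported. Minimum 8 pairs.
- **Hill**: ATP = plateau·Ca^n/(K^n + Ca^n), bounded least squares with
  multistart over n ∈ geomspace(0.3, 8); bootstrap percentile CIs; a
  warning when the data do not span the half-saturation point (n is then
  poorly identified). Minimum 5 positive pairs.
- **changepoint**: continuous hinge fit by grid search over 41 quantiles
  of Ca mass (5th–95th percentile), least squares per candidate; a
  warning when the hinge barely improves on a single line or sits at the
  grid boundary (no clear kink). Minimum 10 pairs.
- **exponential**: y = scale·e^(rate·x) by nonlinear least squares with
  log-linear initialization and a direct fallback when y ≤ 0 samples
  break the log transform.

Recovery tolerances are fixed in the acceptance tests: two-line slopes
within 10%, changepoint threshold within 15% and slopes within ±0.05,
Hill coefficients within ±0.3 (high) and ±0.15 (low) at n = 200 pairs
and 5% multiplicative noise.

## Population statistics (`popstats`)

- **Gaussian mixture / BIC** (k up to 4, 10 initializations) with an
  equal-density crossing between the two selected components as the
  classification threshold.
- **Hartigan's dip** implemented from the definition (iterative greatest
  convex minorant / least concave majorant algorithm, returning
  dip/(2n)); the p-value is bootstrapped against uniform null samples
  (the least favorable unimodal null). The implementation is verified in
  the tests against an independent linear-programming oracle that
  maximizes unimodal-CDF proximity directly, and against closed-form
  cases (equally spaced grid → 1/(2n); two half-weight point masses →
  0.25).
- **gap statistic** and **silhouette at k = 2** as convergent-evidence
  diagnostics.
- **Hierarchical inference**: per-cell values are summarized per animal
  first; groups are compared on per-animal means with Welch's t (2
  groups) or Welch's ANOVA + Games–Howell (≥3), after a Brown–Forsythe
  variance screen. The tests demonstrate the motivation directly: naive
  per-cell testing inflates type-I error several-fold under animal-level
  variance, while the nested procedure stays near nominal, and Welch's
  type-I error under a heteroskedastic null (SD ratio 3, n = 6 per
  group) is required to lie in [0.035, 0.065] over 2000 replicates.

## Artifact control (`artifact_control`)

Two quantitative controls:

- **z-step excursion**: the peak |deviation from 1| of each normalized
  channel inside the imposed defocus interval; the sensor-to-ratio
  excursion ratio is the common-mode suppression factor (required ≥10×
  when the artifact dominates the noise floor).
- **amplitude regression**: per-event ΔF/F₀ vs ΔR/R₀ read at the same
  sample, averaged over a 9-sample window around the peak and
  polarity-signed. The windowed, signed read matters: single-sample
  reads put independent noise on both axes (errors-in-variables slope
  attenuation), and folding small noisy amplitudes through zero flattens
  the slope. A slope near 1 with high R² certifies that the reference
  channel saw none of the biological signal; the acceptance test
  requires the slope pooled over 150 contaminated traces to lie in
  [0.95, 1.10].

## Puncta (`puncta`)

Median filter (disk radius 2 px) → rolling-ball background subtraction
(radius 30 px) → h-maxima local peaks at a prominence threshold
(default 5× the robust background SD via MAD) → per-ROI densities per
mm². Peak regions are labeled with 8-connectivity because the median
filter can split a radially symmetric spot into a diagonal ring of equal
maxima that must count once. The acceptance test requires total counts
over 20 simulated fields to fall inside the 95% Poisson band of the
generating density.

## Pipeline (`pipeline`)

A run is a plain dictionary (optionally from YAML) merged over
`DEFAULT_CONFIG`; unknown keys are rejected with their full field path.
The config hash is the first 16 hex digits of the SHA-256 of the
key-sorted JSON serialization, so key order does not matter. Per-stage
seeds are `sha256(f"{master}:{stage}") % 2^31`, making every stage
independently reproducible and all seeds valid for NumPy. Per-trace
analysis failures (and unreadable input files) are logged and recorded
in the report without aborting the run. Reruns with the same config are
byte-identical, which the tests check file-by-file.

## Limitations

- The generator produces ROI-averaged traces, not spatial rasters;
  spatially localized events and spatial artifact gradients are out of
  scope.
- Single-event amplitude and t₁/₂ readings are noise-biased (see
  Kinetics); use `averaged_kinetics` on noisy data. Residual bias
  remains at very low SNR because alignment itself is estimated.
- The calibration constants are treated as exact; uncertainty in Kd and
  Rf propagates directly into concentration estimates and is not
  modeled.
- The dip p-value uses a uniform bootstrap null, which is conservative
  for peaked unimodal alternatives.
- The two-line mixture assumes exactly one or two linear regimes with
  Gaussian residuals; heavier-tailed noise can flip the BIC choice.
- Changepoint search is restricted to the 5th–95th percentile grid of
  observed Ca masses; thresholds outside the sampled range are not
  identifiable.
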