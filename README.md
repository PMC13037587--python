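# beatlock

Analysis toolkit for beat-locked ATP and Ca²⁺ fluorescence transients in
pacemaker cardiomyocytes, from raw dual-channel line-scan recordings to
event catalogs, kinetics, calibrated ATP concentrations, Ca²⁺→ATP
transfer-function phenotypes, population-level bimodality statistics,
and puncta densities on projected images — together with a fully seeded
synthetic-data generator that stands in for microscopy recordings.

## Scientific problem

Sinoatrial-node pacemaker cells fire spontaneously several times per
second, and each action potential triggers a Ca²⁺ transient that in turn
perturbs cytosolic and mitochondrial ATP on a beat-by-beat timescale.
Genetically encoded ATP sensors make these transients visible as small
(a few percent ΔF/F₀) deflections riding on a noisy, drifting baseline,
in two polarities: positive transients (net ATP production, "Mode 1")
and negative dips (net consumption, "Mode 2"). Extracting biology from
such recordings requires solving several coupled problems:

- detecting small stereotyped events at a known pacing rate without
  being fooled by photon noise or focus drift;
- correcting motion/defocus artifacts with an ATP-insensitive reference
  channel (ratiometric R/R₀ correction) and *proving* the correction
  works (common-mode suppression, ΔF/F₀-vs-ΔR/R₀ amplitude regression);
- converting fluorescence to absolute ATP concentration through the
  sensor's binding curve (Fmax equation);
- quantifying per-event kinetics (time to peak, decay t₁/₂, duration,
  time-integrated "signal mass") and per-cell Ca²⁺-mass → ATP-mass
  transfer functions (two-regime linear mixtures, Hill cooperativity,
  changepoint thresholds);
- testing whether per-cell phenotypes form discrete classes (mixture
  models, Hartigan's dip, gap statistic) while respecting the animal —
  not the cell — as the unit of inference (hierarchical summaries,
  Welch/Games–Howell tests);
- counting expression puncta on projected images as a density per mm².

The package implements each stage as an independently testable module
plus an end-to-end pipeline with seeded, byte-reproducible runs.

## Model

Synthetic recordings are built from a small set of explicit models, so
every analysis routine can be validated against known ground truth:

- **Transient kernel** — linear rise over the time-to-peak, then a
  two-phase exponential decay: the first rate reaches 50% of the
  amplitude at the nominal t₁/₂, the second lands the 5% endpoint at the
  event duration (default: the natural single-rate endpoint
  ttp + log₂(20)·t₁/₂).
- **Beat train** — events at a fixed pacing frequency with Gaussian
  timing jitter, optional per-event amplitude dispersion, and a fixed
  Ca²⁺→ATP lag.
- **Sensor** — single-site binding: F/Fmax = (ATP + Kd/Rf)/(ATP + Kd),
  inverted exactly by the calibration routine
  ATP = Kd·(F/Fmax − 1/Rf)/(1 − F/Fmax).
- **Artifacts** — multiplicative common-mode contamination (slow
  sinusoid or an imposed defocus z-step) applied identically to sensor
  and reference channels, plus additive Gaussian noise per channel.
- **Coupling** — per-event (Ca mass, ATP mass) pairs drawn from linear,
  two-regime linear, Hill, piecewise-linear, or exponential transfer
  functions with multiplicative noise.

See [docs/methods.md](docs/methods.md) for the estimation methods,
parameter defaults and their rationale, and known limitations.

## Worked example

```python
from beatlock import (
    ArtifactSpec, BeatTrainSpec, CouplingSpec, SensorModel, TransientSpec,
    atp_from_f, averaged_kinetics, compute_kinetics, detect_events,
    fit_two_line, generate_event_pairs, generate_linescan, normalize_f0,
    normalize_trace, ratio_correct, trace_summary,
)
from beatlock.simgen import forward_sensor

# 1. simulate a paced dual-channel recording (4.2 s at 3.5 Hz)
trace, truth = generate_linescan(
    BeatTrainSpec(frequency_hz=3.5, record_duration_s=4.2),
    ca=TransientSpec(amplitude=0.5, time_to_peak_ms=80.0, decay_t_half_ms=40.0),
    atp=TransientSpec(amplitude=0.2, time_to_peak_ms=67.85, decay_t_half_ms=20.55),
    artifact=ArtifactSpec(common_mode_amplitude=0.05, noise_sd=0.01),
    seed=7)

# 2. normalize, ratio-correct against the reference channel, detect
norm = normalize_trace(trace)
rr = normalize_f0(ratio_correct(norm.by_role("sensor"),
                                norm.by_role("reference")))
events = [e for e in detect_events(rr) if e.polarity == 1]
records = [compute_kinetics(e, rr, trace.dt_ms) for e in events]
summary = trace_summary(records, trace.n_samples * trace.dt_ms / 1000.0)
print(f"detected {len(events)} ATP transients "
      f"(ground truth: {(truth.channel == 'atp').sum()})")
print(f"event frequency: {summary['frequency_hz']:.2f} Hz")

# 3. beat-averaged kinetics (noise-robust per-trace summary)
rec = averaged_kinetics(rr, events, trace.dt_ms)
print(f"beat-averaged amplitude {rec.amplitude:.3f}, "
      f"time-to-peak {rec.time_to_peak_ms:.1f} ms, "
      f"decay t1/2 {rec.decay_t_half_ms:.1f} ms")

# 4. calibrate a diastolic fluorescence level to [ATP]
sensor = SensorModel(kd_uM=1460.0, rf=3.8, fmax=1000.0)
f_dia = forward_sensor(839.9, sensor) * sensor.fmax
print(f"diastolic F = {f_dia:.1f} AU  ->  "
      f"[ATP] = {float(atp_from_f(f_dia, sensor)):.1f} uM")

# 5. fit a two-regime Ca->ATP transfer function on event pairs
pairs = generate_event_pairs(CouplingSpec.two_line((1.02, 0.12)),
                             200, 0.05, seed=1)
fit = fit_two_line(pairs, seed=0)
print(f"two-line fit: slopes {fit.params['slope_high']:.3f} / "
      f"{fit.params['slope_low']:.3f}  (R2 {fit.r2:.3f})")
```

Output:

```
detected 15 ATP transients (ground truth: 15)
event frequency: 3.57 Hz
beat-averaged amplitude 0.195, time-to-peak 66.2 ms, decay t1/2 22.1 ms
diastolic F = 532.2 AU  ->  [ATP] = 839.9 uM
two-line fit: slopes 1.016 / 0.120  (R2 0.996)
```

The generator injected 15 transients with amplitude 0.2, time-to-peak
67.85 ms and decay t₁/₂ 20.55 ms; the beat-averaged readout recovers
them within a few percent at 1% per-channel noise, and the calibration
round-trips the 839.9 µM ground truth exactly.

## Command line

The `beatlock` console script wraps the same stages:

```bash
beatlock simulate --seed 3 --out sim/          # traces + TIFF + truth
beatlock detect --trace sim/sim0.csv --channel atp --out events.csv
beatlock couple --pairs pairs.csv --model two_line
beatlock popstats --values volumes.csv
beatlock puncta --image field.tif
beatlock run-all --config run.yaml --out results/
```

`run-all` merges the YAML config over documented defaults (unknown keys
are rejected with their full path), derives one sub-seed per stage from
the master seed, tolerates per-trace failures, and writes an output set
(events, kinetics, per-trace summaries, event pairs, `report.json` with
the config hash) that is byte-identical on rerun.

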