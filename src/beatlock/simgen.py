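"""Synthetic beat-locked recording generator and the sensor forward model.

Emulates the statistical structure of dual-channel line-scan recordings from
pacemaker tissue: periodic beat trains driving Ca2+ transients, ATP-sensor
transients coupled to each Ca2+ event (positive Mode 1 "gain" deflections or
negative Mode 2 "dips"), common-mode optical artifacts shared with a
reference channel, axial-defocus (z-step) excursions, multiplicative shot
noise, bimodal per-cell populations, and puncta fields of known density.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trace import Trace

# 5%-of-amplitude truncation shared by the kernel and the duration
# endpoint used in kinetics extraction.
KERNEL_TAIL_FRACTION = 0.05
# log2(1/0.05): half-lives needed for an exponential to decay to 5%
_LOG2_20 = math.log2(20.0)
# fractional fluorescence loss per µm of axial defocus (5 µm -> 20% drop)
ZSTEP_DROP_PER_UM = 0.04
# frequency of the smooth common-mode artifact waveform, Hz
COMMON_MODE_HZ = 0.8


# --------------------------------------------------------------------- types
@dataclass
class SensorModel:
    """Single-site binding model of the intracellular ATP sensor.

    kd_uM : apparent dissociation constant (µM); rf : dynamic range
    Fmax/Fmin; fmax : fluorescence at saturating ATP (arbitrary units).
    """

    kd_uM: float = 1460.0
    rf: float = 3.8
    fmax: float = 1000.0

    def __post_init__(self):
        if self.kd_uM <= 0:
            raise ValueError("Kd must be positive")
        if self.rf <= 1:
            raise ValueError("Rf must exceed 1")
        if self.fmax <= 0:
            raise ValueError("Fmax must be positive")


@dataclass
class TransientSpec:
    """Shape of one stereotyped transient in ΔF/F0 units.

    amplitude is the peak |ΔF/F0|; polarity +1 for positive (Mode 1 /
    cytosolic) transients, -1 for Mode 2 dips. Times in ms. When
    ``duration_ms`` is omitted it defaults to the natural endpoint of a
    single-rate exponential decay, time_to_peak + log2(20)*decay_t_half.
    """

    amplitude: float
    time_to_peak_ms: float
    decay_t_half_ms: float
    duration_ms: float | None = None
    polarity: int = 1
    amplitude_cv: float = 0.0   # per-event amplitude dispersion

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if self.time_to_peak_ms <= 0 or self.decay_t_half_ms <= 0:
            raise ValueError("time_to_peak and decay_t_half must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.duration_ms is None:
            self.duration_ms = self.time_to_peak_ms + _LOG2_20 * self.decay_t_half_ms
        if not self.time_to_peak_ms < self.duration_ms:
            raise ValueError("time_to_peak must be smaller than duration")
        if self.duration_ms <= self.time_to_peak_ms + self.decay_t_half_ms:
            raise ValueError(
                "duration must exceed time_to_peak + decay_t_half "
                "(the waveform must cross half amplitude before its endpoint)"
            )


@dataclass
class BeatTrainSpec:
    """Timing of the periodic beat train driving the transients."""

    frequency_hz: float = 3.5
    record_duration_s: float = 4.2
    jitter_sd_ms: float = 0.0
    ca_to_atp_lag_ms: float = 20.0

    def __post_init__(self):
        if self.frequency_hz < 0:
            raise ValueError("frequency must be >= 0")
        if self.record_duration_s <= 0:
            raise ValueError("record_duration must be positive")
        if not 0 <= self.ca_to_atp_lag_ms < 50:
            raise ValueError("ca_to_atp_lag must lie in [0, 50) ms")


@dataclass
class CouplingSpec:
    """Ca2+ signal mass -> ATP signal mass transfer law.

    kind is one of {"linear", "two_line", "hill", "piecewise",
    "exponential"}; use the class-method constructors.
    """

    kind: str
    slopes: tuple = (1.0,)
    intercepts: tuple = (0.0,)
    weights: tuple = (1.0,)
    hill_n: float = 1.0
    hill_k: float = 1500.0
    plateau: float = 2000.0
    threshold: float = 2000.0
    scale: float = 1.0
    rate: float = 0.0

    @classmethod
    def linear(cls, slope: float, intercept: float = 0.0) -> "CouplingSpec":
        return cls(kind="linear", slopes=(slope,), intercepts=(intercept,))

    @classmethod
    def two_line(cls, slopes, intercepts=(0.0, 0.0), weights=(0.5, 0.5)) -> "CouplingSpec":
        """Two linear gain regimes mixed with the given weights."""
        if len(slopes) != 2:
            raise ValueError("two_line requires exactly two slopes")
        return cls(kind="two_line", slopes=tuple(slopes),
                   intercepts=tuple(intercepts), weights=tuple(weights))

    @classmethod
    def hill(cls, n: float, k: float, plateau: float) -> "CouplingSpec":
        if n <= 0 or k <= 0:
            raise ValueError("Hill n and K must be positive")
        return cls(kind="hill", hill_n=n, hill_k=k, plateau=plateau)

    @classmethod
    def piecewise(cls, threshold: float, slope_below: float,
                  slope_above: float, intercept: float = 0.0) -> "CouplingSpec":
        """Continuous two-segment line with a kink at ``threshold`` AU."""
        if threshold <= 0:
            raise ValueError("piecewise threshold must be positive")
        return cls(kind="piecewise", threshold=threshold,
                   slopes=(slope_below, slope_above), intercepts=(intercept,))

    @classmethod
    def exponential(cls, scale: float, rate: float) -> "CouplingSpec":
        return cls(kind="exponential", scale=scale, rate=rate)

    def apply(self, ca, regime=None):
        """Evaluate the noiseless transfer law at Ca signal mass ``ca``.

        For two_line couplings ``regime`` (0 = first slope, 1 = second)
        selects the branch per element; it is ignored otherwise.
        """
        ca = np.asarray(ca, dtype=float)
        if self.kind == "linear":
            return self.slopes[0] * ca + self.intercepts[0]
        if self.kind == "two_line":
            if regime is None:
                raise ValueError("two_line coupling requires a regime array")
            regime = np.asarray(regime, dtype=int)
            slopes = np.asarray(self.slopes)[regime]
            icpts = np.asarray(self.intercepts)[regime]
            return slopes * ca + icpts
        if self.kind == "hill":
            cn = np.power(ca, self.hill_n)
            return self.plateau * cn / (self.hill_k ** self.hill_n + cn)
        if self.kind == "piecewise":
            b0, b1 = self.slopes
            base = self.intercepts[0]
            return np.where(
                ca <= self.threshold,
                base + b0 * ca,
                base + b0 * self.threshold + b1 * (ca - self.threshold),
            )
        if self.kind == "exponential":
            return self.scale * np.exp(self.rate * ca)
        raise ValueError(f"unknown coupling kind {self.kind!r}")


@dataclass
class ArtifactSpec:
    """Optical artifact model shared by sensor and reference channels."""

    common_mode_amplitude: float = 0.0
    zstep_depth_um: float = 0.0
    zstep_duration_s: float = 0.5
    zstep_onset_s: float = 0.0
    noise_sd: float = 0.02

    def __post_init__(self):
        for name in ("common_mode_amplitude", "zstep_depth_um",
                     "zstep_duration_s", "zstep_onset_s", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MixturePopulationSpec:
    """Gaussian-mixture population, e.g. bimodal mitochondrial volumes."""

    weights: tuple
    means: tuple
    sds: tuple
    n_samples: int
    seed: int = 0

    def __post_init__(self):
        if len(self.weights) == 0:
            raise ValueError("at least one mixture component is required")
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds must have equal length")
        if not math.isclose(sum(self.weights), 1.0, rel_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be >= 0")


# Phenomenological drug presets: labels for integration tests, not
# pharmacokinetics. Ivabradine slows the beat rate; thapsigargin and FCCP
# abolish Ca-driven transients.
DRUG_PRESETS = {
    "ivabradine": {"frequency_factor": 0.65, "amplitude_factor": 1.0},
    "thapsigargin": {"frequency_factor": 1.0, "amplitude_factor": 0.0},
    "fccp": {"frequency_factor": 1.0, "amplitude_factor": 0.0},
}


def apply_drug_preset(name: str, beats: BeatTrainSpec,
                      *transients: TransientSpec):
    """Return (beats, transients...) with a drug preset's scaling applied."""
    preset = DRUG_PRESETS[name]
    beats = BeatTrainSpec(
        frequency_hz=beats.frequency_hz * preset["frequency_factor"],
        record_duration_s=beats.record_duration_s,
        jitter_sd_ms=beats.jitter_sd_ms,
        ca_to_atp_lag_ms=beats.ca_to_atp_lag_ms,
    )
    out = [
        TransientSpec(
            amplitude=t.amplitude * preset["amplitude_factor"],
            time_to_peak_ms=t.time_to_peak_ms,
            decay_t_half_ms=t.decay_t_half_ms,
            duration_ms=t.duration_ms,
            polarity=t.polarity,
        )
        for t in transients
    ]
    return (beats, *out)


# ------------------------------------------------------------ sensor model
def forward_sensor(atp_uM, sensor: SensorModel):
    """Normalized fluorescence F/Fmax of the sensor at a given [ATP].

    Algebraic inverse of the calibration equation
    ATP = Kd (F/Fmax - 1/Rf) / (1 - F/Fmax):

        F/Fmax = (ATP + Kd/Rf) / (ATP + Kd)

    Monotone increasing from 1/Rf at zero ATP toward 1 at saturation.
    """
    atp = np.asarray(atp_uM, dtype=float)
    if np.any(atp < 0):
        raise ValueError("ATP concentration must be >= 0")
    f = (atp + sensor.kd_uM / sensor.rf) / (atp + sensor.kd_uM)
    return f if f.ndim else float(f)


# --------------------------------------------------------- transient kernel
def transient_kernel(spec: TransientSpec, dt_ms: float) -> np.ndarray:
    """Sampled ΔF/F0 waveform of one transient (signed by polarity).

    Linear rise from onset to peak over ``time_to_peak_ms``, then a
    two-phase exponential decay: the stated half-life until 50% of the
    amplitude is lost, then a second rate chosen so the 5%-of-amplitude
    endpoint falls exactly at ``duration_ms``. This preserves all three
    kinetic observables (time to peak, decay t1/2, duration) at once.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if dt_ms > spec.time_to_peak_ms / 4:
        raise ValueError("dt must be <= time_to_peak/4 to resolve the rise")
    a, ttp, h = spec.amplitude, spec.time_to_peak_ms, spec.decay_t_half_ms
    dur = spec.duration_ms
    # second-phase half-life: from 0.5A at ttp+h down to 0.05A at dur
    h2 = (dur - ttp - h) / math.log2(10.0)
    t = np.arange(0.0, dur + dt_ms / 2, dt_ms)
    y = np.zeros_like(t)
    rising = t <= ttp
    y[rising] = a * t[rising] / ttp
    td = t[~rising] - ttp
    phase1 = td <= h
    dec = np.empty_like(td)
    dec[phase1] = a * np.power(2.0, -td[phase1] / h)
    dec[~phase1] = 0.5 * a * np.power(2.0, -(td[~phase1] - h) / h2)
    y[~rising] = dec
    y[t > dur] = 0.0
    return spec.polarity * y


def kernel_signal_mass(spec: TransientSpec) -> float:
    """Closed-form time integral of the kernel, in ΔF/F0 · ms (signed)."""
    a, ttp, h = spec.amplitude, spec.time_to_peak_ms, spec.decay_t_half_ms
    h2 = (spec.duration_ms - ttp - h) / math.log2(10.0)
    ln2 = math.log(2.0)
    rise = 0.5 * a * ttp
    phase1 = a * (h / ln2) * (1.0 - 0.5)
    phase2 = 0.5 * a * (h2 / ln2) * (1.0 - KERNEL_TAIL_FRACTION * 2.0)
    return spec.polarity * (rise + phase1 + phase2)


# ------------------------------------------------------------- generators
def generate_linescan(
    beats: BeatTrainSpec,
    ca: TransientSpec,
    atp: TransientSpec,
    coupling: CouplingSpec | None = None,
    artifact: ArtifactSpec | None = None,
    dt_ms: float = 2.0,
    seed: int = 0,
    f0: float = 1000.0,
    include_reference: bool = True,
    extent_um: float | None = None,
):
    """Simulate a dual-channel line-scan recording with ground truth.

    One Ca2+ transient is placed per beat; each drives one ATP event at a
    fixed lag below 50 ms. When a ``coupling`` law is given, the ATP
    kernel is rescaled so its signal mass equals the law applied to the
    Ca event's signal mass. Artifacts (common-mode fluctuation, z-step
    defocus, multiplicative noise) hit every channel; the reference
    channel carries artifacts only.

    Returns
    -------
    (Trace, DataFrame)
        The trace (channels ``ca``, ``atp`` and optionally ``ref``) in
        raw fluorescence units, and a tidy ground-truth event table with
        columns channel, onset_s, peak_s, amplitude, polarity, signal_mass.
    """
    artifact = artifact or ArtifactSpec(common_mode_amplitude=0.0, noise_sd=0.0)
    rng = np.random.default_rng(seed)
    n = int(round(beats.record_duration_s * 1000.0 / dt_ms))
    t_ms = np.arange(n) * dt_ms

    truth_rows = []
    d_ca = np.zeros(n)
    d_atp = np.zeros(n)
    if beats.frequency_hz > 0:
        period_ms = 1000.0 / beats.frequency_hz
        if max(ca.duration_ms, atp.duration_ms) > period_ms:
            warnings.warn(
                "transient duration exceeds the beat period; "
                "events overlap", stacklevel=2,
            )
        onsets = np.arange(0.0, beats.record_duration_s * 1000.0, period_ms)
        if beats.jitter_sd_ms > 0:
            onsets = onsets + rng.normal(0.0, beats.jitter_sd_ms, onsets.size)
            onsets = np.sort(onsets)
        onsets = onsets[(onsets >= 0) & (onsets < beats.record_duration_s * 1000.0)]
        ca_kernel = transient_kernel(ca, dt_ms)
        atp_kernel = transient_kernel(atp, dt_ms)
        ca_mass = kernel_signal_mass(ca)
        atp_mass = kernel_signal_mass(atp)
        for onset in onsets:
            ca_scale = 1.0
            if ca.amplitude_cv > 0:
                ca_scale = max(0.1, 1.0 + rng.normal(0.0, ca.amplitude_cv))
            i0 = int(round(onset / dt_ms))
            seg = min(ca_kernel.size, n - i0)
            if seg <= 0:
                continue
            d_ca[i0:i0 + seg] += ca_scale * ca_kernel[:seg]
            truth_rows.append({
                "channel": "ca",
                "onset_s": i0 * dt_ms / 1000.0,
                "peak_s": (i0 * dt_ms + ca.time_to_peak_ms) / 1000.0,
                "amplitude": ca.amplitude * ca_scale,
                "polarity": ca.polarity,
                "signal_mass": ca_mass * ca_scale,
            })
            a_onset = onset + beats.ca_to_atp_lag_ms
            j0 = int(round(a_onset / dt_ms))
            sega = min(atp_kernel.size, n - j0)
            if sega <= 0:
                continue
            if coupling is not None:
                target = float(coupling.apply(abs(ca_mass) * ca_scale))
                scale = target / abs(atp_mass) if atp_mass else 0.0
            elif atp.amplitude_cv > 0:
                scale = max(0.1, 1.0 + rng.normal(0.0, atp.amplitude_cv))
            else:
                scale = 1.0
            d_atp[j0:j0 + sega] += scale * atp_kernel[:sega]
            truth_rows.append({
                "channel": "atp",
                "onset_s": j0 * dt_ms / 1000.0,
                "peak_s": (j0 * dt_ms + atp.time_to_peak_ms) / 1000.0,
                "amplitude": atp.amplitude * abs(scale),
                "polarity": atp.polarity,
                "signal_mass": atp_mass * scale,
            })

    # shared optical artifacts
    common = artifact.common_mode_amplitude * np.sin(
        2.0 * math.pi * COMMON_MODE_HZ * t_ms / 1000.0
    )
    zdrop = np.zeros(n)
    if artifact.zstep_depth_um > 0:
        in_step = (t_ms / 1000.0 >= artifact.zstep_onset_s) & (
            t_ms / 1000.0 < artifact.zstep_onset_s + artifact.zstep_duration_s
        )
        zdrop[in_step] = min(ZSTEP_DROP_PER_UM * artifact.zstep_depth_um, 0.95)

    def channel(delta):
        clean = f0 * (1.0 + delta) * (1.0 + common) * (1.0 - zdrop)
        if artifact.noise_sd > 0:
            clean = clean * (1.0 + rng.normal(0.0, artifact.noise_sd, n))
        return clean

    rows = [channel(d_ca), channel(d_atp)]
    names = ["ca", "atp"]
    roles = {"ca": "calcium", "atp": "sensor"}
    if include_reference:
        rows.append(channel(np.zeros(n)))
        names.append("ref")
        roles["ref"] = "reference"

    trace = Trace(np.vstack(rows), dt_ms, tuple(names), roles,
                  extent_um=extent_um)
    truth = pd.DataFrame(
        truth_rows,
        columns=["channel", "onset_s", "peak_s", "amplitude", "polarity",
                 "signal_mass"],
    )
    return trace, truth


def generate_event_pairs(
    coupling: CouplingSpec,
    n: int,
    noise_cv: float,
    seed: int = 0,
    ca_range: tuple = (200.0, 6000.0),
) -> pd.DataFrame:
    """Draw (Ca signal mass, ATP signal mass) event pairs under a coupling law.

    Ca masses are uniform over ``ca_range``; ATP masses follow the law with
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.
    For two-line couplings each pair is assigned a regime by the coupling
    law's mixing weights (recorded in the ``regime`` column).
    """
    if n < 2:
        raise ValueError("at least two pairs are required")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    ca = rng.uniform(ca_range[0], ca_range[1], n)
    if coupling.kind == "two_line":
        regime = (rng.random(n) < coupling.weights[1]).astype(int)
        atp = coupling.apply(ca, regime=regime)
    else:
        regime = np.zeros(n, dtype=int)
        atp = coupling.apply(ca)
    if noise_cv > 0:
        atp = atp * (1.0 + rng.normal(0.0, noise_cv, n))
    return pd.DataFrame({"ca_mass": ca, "atp_mass": atp, "regime": regime})


def generate_population(spec: MixturePopulationSpec) -> np.ndarray:
    """Draw i.i.d. samples from a Gaussian mixture (e.g. bimodal volumes)."""
    if spec.n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(spec.seed)
    comp = rng.choice(len(spec.weights), size=spec.n_samples, p=spec.weights)
    means = np.asarray(spec.means, dtype=float)
    sds = np.asarray(spec.sds, dtype=float)
    return rng.normal(means[comp], sds[comp])


def generate_puncta_image(
    density_per_mm2: float,
    size_px: tuple = (256, 256),
    um_per_px: float = 0.5,
    psf_sigma_px: float = 1.5,
    spot_amplitude: float = 100.0,
    background_offset: float = 20.0,
    background_gradient: tuple = (0.0, 0.0),
    noise_sd: float = 2.0,
    seed: int = 0,
):
    """Poisson-placed Gaussian spots on a smooth background.

    Returns (image, truth) where truth is a DataFrame of spot centers in
    pixel coordinates (row, col). The spot count is Poisson with mean
    density x field area; positions are uniform.
    """
    if density_per_mm2 < 0:
        raise ValueError("density must be >= 0")
    if um_per_px <= 0:
        raise ValueError("µm per pixel must be positive")
    rng = np.random.default_rng(seed)
    h, w = size_px
    area_mm2 = h * w * (um_per_px / 1000.0) ** 2
    n_spots = rng.poisson(density_per_mm2 * area_mm2)
    rows = rng.uniform(0, h, n_spots)
    cols = rng.uniform(0, w, n_spots)

    yy, xx = np.mgrid[0:h, 0:w]
    img = (background_offset
           + background_gradient[0] * yy
           + background_gradient[1] * xx).astype(float)
    half = int(math.ceil(4 * psf_sigma_px))
    for r, c in zip(rows, cols):
        r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
        sub_y = yy[r0:r1, c0:c1]
        sub_x = xx[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += spot_amplitude * np.exp(
            -((sub_y - r) ** 2 + (sub_x - c) ** 2) / (2 * psf_sigma_px ** 2)
        )
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    truth = pd.DataFrame({"row": rows, "col": cols})
    return img, truth
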