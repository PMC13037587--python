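"""Per-event kinetics and the signal-mass family of statistics.

Kinetic observables per transient: time to peak, decay t1/2 (time after
the peak for the excursion to lose half its amplitude, by linear
interpolation between samples) and total duration (onset to the return
within 5% of amplitude toward baseline, the same endpoint the synthetic
kernel uses). Signal mass is the time-integrated change in normalized
fluorescence over the event (trapezoidal, ΔF/F0 · ms, signed by
polarity; multiplied by the line extent in µm for spatially extended
events). Per-trace statistics: event frequency (count / record length)
and signal mass rate (total mass / record length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import Event
from .simgen import KERNEL_TAIL_FRACTION


@dataclass
class KineticsRecord:
    """Kinetic parameters of one event; missing t1/2 or duration is NaN."""

    event_id: int
    polarity: int
    amplitude: float
    time_to_peak_ms: float
    decay_t_half_ms: float
    duration_ms: float
    signal_mass: float
    flags: tuple = ()


def _cross_forward(dev: np.ndarray, start: int, level: float,
                   dt_ms: float) -> float:
    """Time (ms after ``start``) at which |deviation| first falls to
    ``level``, linearly interpolated; NaN if it never does."""
    for j in range(start + 1, dev.size):
        if dev[j] <= level:
            d0, d1 = dev[j - 1], dev[j]
            frac = (d0 - level) / (d0 - d1) if d1 < d0 else 0.0
            return ((j - 1) + frac - start) * dt_ms
    return math.nan


def _onset_time_ms(dev: np.ndarray, event: Event, amp: float,
                   dt_ms: float) -> float:
    """Onset time (ms, absolute) by extrapolating the rising limb.

    Finds the interpolated crossing of 5% of amplitude on the rise and
    extends the line through it and the peak down to baseline, which is
    exact for a linear rise and insensitive to the detector's onset
    placement. Falls back to the detected onset if the rise never dips
    below 5% of amplitude inside the event.
    """
    level = KERNEL_TAIL_FRACTION * amp
    for j in range(event.peak_idx, event.onset_idx, -1):
        if dev[j - 1] <= level:
            d0, d1 = dev[j - 1], dev[j]
            frac = (level - d0) / (d1 - d0) if d1 > d0 else 0.0
            t5 = (j - 1 + frac) * dt_ms
            t_peak = event.peak_idx * dt_ms
            return t5 - (t_peak - t5) * KERNEL_TAIL_FRACTION / (1.0 - KERNEL_TAIL_FRACTION)
    return event.onset_idx * dt_ms


def compute_kinetics(event: Event, ffo: np.ndarray, dt_ms: float,
                     extent_um: float | None = None) -> KineticsRecord:
    """Kinetic parameters of one event on its normalized trace.

    The half-decay and duration endpoints are searched forward from the
    peak on the full trace (they may extend past the detector's offset),
    stopping at the trace end. Mode 2 dips use the identical formulas on
    |F/F0 - 1|.
    """
    x = np.asarray(ffo, dtype=float) - 1.0
    if not 0 <= event.onset_idx < event.peak_idx < event.offset_idx < x.size:
        raise ValueError("event indices outside the trace")
    dev = event.polarity * x
    amp = dev[event.peak_idx]
    flags = []
    onset_ms = _onset_time_ms(dev, event, amp, dt_ms)

    t_half = _cross_forward(dev, event.peak_idx, amp / 2.0, dt_ms)
    if math.isnan(t_half):
        flags.append("t_half_not_reached")
    tail = _cross_forward(dev, event.peak_idx, KERNEL_TAIL_FRACTION * amp, dt_ms)
    if math.isnan(tail):
        flags.append("duration_endpoint_not_reached")
        duration = math.nan
    else:
        duration = event.peak_idx * dt_ms + tail - onset_ms

    return KineticsRecord(
        event_id=event.event_id,
        polarity=event.polarity,
        amplitude=float(amp),
        time_to_peak_ms=event.peak_idx * dt_ms - onset_ms,
        decay_t_half_ms=t_half,
        duration_ms=duration,
        signal_mass=signal_mass(event, ffo, dt_ms, extent_um),
        flags=tuple(flags),
    )


def signal_mass(event: Event, ffo: np.ndarray, dt_ms: float,
                extent_um: float | None = None) -> float:
    """Time-integrated ΔF/F0 over [onset, offset], trapezoidal, in AU.

    AU means ΔF/F0 · ms for 1-D traces, additionally x µm when a line
    extent is supplied. The sign follows the event polarity: Mode 2
    deficits integrate negative.
    """
    x = np.asarray(ffo, dtype=float) - 1.0
    seg = x[event.onset_idx:event.offset_idx + 1]
    mass = float(np.trapezoid(seg, dx=dt_ms))
    if extent_um is None and event.area_um is not None:
        extent_um = event.area_um
    if extent_um is not None:
        mass *= extent_um
    return mass


def signal_mass_rate(masses, record_duration_s: float) -> float:
    """Total signal mass per trace divided by the recording time (AU/s)."""
    if record_duration_s <= 0:
        raise ValueError("record duration must be positive")
    return float(np.sum(masses)) / record_duration_s


def event_frequency(n_events: int, record_duration_s: float) -> float:
    """Event count divided by the record length, in Hz."""
    if record_duration_s <= 0:
        raise ValueError("record duration must be positive")
    return n_events / record_duration_s


def mean_interval_frequency(events, dt_ms: float) -> float:
    """Reciprocal of the mean inter-event onset interval, in Hz.

    Secondary convention reported alongside the count-based frequency;
    NaN with fewer than two events.
    """
    if len(events) < 2:
        return math.nan
    onsets = np.sort([ev.onset_idx for ev in events]) * dt_ms / 1000.0
    return float(1.0 / np.mean(np.diff(onsets)))


def beat_average(ffo, events, smooth_samples: int = 5):
    """Average the beat-locked transients of one trace into a single
    mean transient (F/F0 units) plus the synthetic event spanning it.

    Events are aligned on the peak of a lightly boxcar-smoothed copy of
    the trace (raw-sample maxima are biased toward positive noise
    excursions, which would shorten every downstream decay estimate) and
    the raw deviations are averaged sample-by-sample. Mode 2 dips are
    folded to positive deviations before averaging, so mixed-polarity
    event lists must be split by the caller. Returns
    ``(ffo_mean, event, n_averaged)``.
    """
    if not events:
        raise ValueError("beat averaging requires at least one event")
    if len({ev.polarity for ev in events}) > 1:
        raise ValueError("events must share one polarity; split the list")
    from .events import Event

    x = np.asarray(ffo, dtype=float) - 1.0
    w = max(1, int(smooth_samples))
    sm = np.convolve(x, np.ones(w) / w, mode="same")
    aligns = [ev.onset_idx
              + int(np.argmax(ev.polarity
                              * sm[ev.onset_idx:ev.offset_idx + 1]))
              for ev in events]
    pre = int(np.median([a - ev.onset_idx
                         for a, ev in zip(aligns, events)]))
    post = int(np.median([ev.offset_idx - a
                          for a, ev in zip(aligns, events)]))
    segs = [events[i].polarity * x[a - pre:a + post + 1]
            for i, a in enumerate(aligns)
            if a - pre >= 0 and a + post < x.size]
    if not segs:
        raise ValueError("no event fits inside the trace after alignment")
    mean_dev = np.mean(segs, axis=0)

    pad = max(100, mean_dev.size)       # room for the decay tail search
    out = np.ones(pad + mean_dev.size + pad)
    out[pad:pad + mean_dev.size] += mean_dev
    peak = pad + int(np.argmax(mean_dev))
    event = Event(onset_idx=pad, peak_idx=peak,
                  offset_idx=pad + mean_dev.size - 1 + pad // 2,
                  polarity=1, amplitude=float(out[peak] - 1.0),
                  mean_ffo=float(np.mean(out[pad:pad + mean_dev.size])))
    return out, event, len(segs)


def averaged_kinetics(ffo, events, dt_ms: float,
                      smooth_samples: int = 5) -> KineticsRecord:
    """Kinetics of the beat-averaged transient of one trace.

    Averaging across beats suppresses the noise-driven biases of
    single-event readings (a noisy maximum overestimates amplitude and a
    noisy first crossing fires early, both shortening t1/2), so this is
    the preferred per-trace kinetic summary on noisy recordings.
    """
    mean_ffo, event, _ = beat_average(ffo, events, smooth_samples)
    return compute_kinetics(event, mean_ffo, dt_ms)


def max_sustainable_frequency(duration_ms: float) -> float:
    """Firing-rate ceiling implied by a full transient duration.

    A cell whose ATP drawdown takes ``duration_ms`` to recover can sustain
    at most 1000 / duration_ms beats per second before the next beat
    arrives inside the recovery window.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    return 1000.0 / duration_ms


def kinetics_table(records, dt_ms: float | None = None) -> pd.DataFrame:
    rows = [{
        "event_id": r.event_id,
        "polarity": r.polarity,
        "amplitude": r.amplitude,
        "time_to_peak_ms": r.time_to_peak_ms,
        "decay_t_half_ms": r.decay_t_half_ms,
        "duration_ms": r.duration_ms,
        "signal_mass": r.signal_mass,
        "flags": ";".join(r.flags),
    } for r in records]
    return pd.DataFrame(rows, columns=[
        "event_id", "polarity", "amplitude", "time_to_peak_ms",
        "decay_t_half_ms", "duration_ms", "signal_mass", "flags"])


def trace_summary(records, record_duration_s: float) -> dict:
    """Per-trace summary: frequency, signal mass rate, mode composition."""
    masses = [r.signal_mass for r in records]
    n_pos = sum(1 for r in records if r.polarity > 0)
    n_neg = len(records) - n_pos
    return {
        "n_events": len(records),
        "n_mode1": n_pos,
        "n_mode2": n_neg,
        "frequency_hz": event_frequency(len(records), record_duration_s),
        "signal_mass_rate_au_per_s": signal_mass_rate(masses, record_duration_s),
    }
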