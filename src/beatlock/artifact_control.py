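"""Motion and defocus artifact diagnostics.

Two quantitative controls establish that detected transients are not
optical artifacts: (1) the event-level regression of raw peak amplitudes
ΔF/F0 against ratiometric peak amplitudes ΔR/R0 — a slope near 1 with
high R² means the reference channel saw none of the signal; (2) the
z-step excursion metric — the peak absolute deviation from baseline of
each channel and of the ratiometric trace during an imposed axial-defocus
interval, whose ratio quantifies common-mode suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ArtifactReport:
    slope: float
    intercept: float
    r2: float
    slope_ci: tuple | None = None
    n_events: int = 0
    excursions: dict = field(default_factory=dict)

    def __post_init__(self):
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("R² must lie in [0, 1]")


def amplitude_regression(ffo_amps, rr0_amps, n_boot: int = 1000,
                         seed: int = 0) -> ArtifactReport:
    """OLS of raw event amplitudes ΔF/F0 on ratiometric amplitudes ΔR/R0.

    Amplitudes are paired per event (same sample index in both traces).
    Returns the slope, intercept, R² and a bootstrap percentile 95% CI
    for the slope.
    """
    x = np.asarray(rr0_amps, dtype=float)
    y = np.asarray(ffo_amps, dtype=float)
    if x.size != y.size:
        raise ValueError("amplitude arrays must be paired")
    if x.size < 5:
        raise ValueError("regression requires at least 5 paired events")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the ratiometric amplitudes")
    res = stats.linregress(x, y)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        slopes = np.empty(n_boot)
        idx_all = np.arange(x.size)
        for b in range(n_boot):
            idx = rng.choice(idx_all, size=x.size, replace=True)
            if np.ptp(x[idx]) == 0:
                slopes[b] = res.slope
            else:
                slopes[b] = stats.linregress(x[idx], y[idx]).slope
        ci = tuple(np.percentile(slopes, [2.5, 97.5]))
    return ArtifactReport(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), slope_ci=ci, n_events=x.size)


def event_amplitudes_same_sample(ffo, rr0, events, smooth_samples: int = 9):
    """Paired (ΔF/F0, ΔR/R0) peak amplitudes at the same sample per event.

    Peaks are read at each event's F/F0 peak index in both traces (no
    per-channel re-localization, for determinism), averaged over a short
    window around the peak: single-sample reads put independent noise on
    both variables and attenuate the regression slope (errors in
    variables), while the identical window in both channels leaves the
    slope unbiased.
    """
    ffo = np.asarray(ffo, dtype=float)
    rr0 = np.asarray(rr0, dtype=float)
    half = max(0, smooth_samples // 2)
    out_f, out_r = [], []
    for ev in events:
        lo = max(0, ev.peak_idx - half)
        hi = min(ffo.size, ev.peak_idx + half + 1)
        # polarity-signed deviations rather than absolute values: folding
        # noisy small amplitudes through zero would flatten the regression
        out_f.append(ev.polarity * (float(np.mean(ffo[lo:hi])) - 1.0))
        out_r.append(ev.polarity * (float(np.mean(rr0[lo:hi])) - 1.0))
    return np.asarray(out_f), np.asarray(out_r)


def zstep_excursion(channels: dict, interval_s: tuple, dt_ms: float) -> dict:
    """Peak |deviation from baseline 1.0| inside the z-step interval.

    ``channels`` maps a name (e.g. "sensor", "reference", "ratio") to its
    baseline-normalized trace; the same metric is computed for each.
    """
    i0 = int(round(interval_s[0] * 1000.0 / dt_ms))
    i1 = int(round(interval_s[1] * 1000.0 / dt_ms))
    out = {}
    for name, trace in channels.items():
        x = np.asarray(trace, dtype=float)
        if not 0 <= i0 < i1 <= x.size:
            raise ValueError("z-step interval outside the record")
        out[name] = float(np.max(np.abs(x[i0:i1] - 1.0)))
    return out


def suppression_factor(excursions: dict, sensor: str = "sensor",
                       ratio: str = "ratio") -> float:
    """How strongly ratiometry suppressed the sensor-channel excursion."""
    denom = excursions[ratio]
    return float("inf") if denom == 0 else excursions[sensor] / denom
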