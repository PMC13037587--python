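"""Normalization and artifact-correction transforms for raw traces.

Implements F/F0 baseline normalization, ratiometric R/R0 correction
against an ATP-insensitive reference channel, the frame-wise rolling-F0
high-pass used for frame-series recordings, and background-subtracted ROI
means for 2-D images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.ndimage import gaussian_filter1d

from .trace import Trace


@dataclass
class BaselineDef:
    """How the baseline fluorescence F0 is estimated.

    method "mode" (default) locates the peak of the sample density — the
    diastolic cluster — which stays unbiased under noise, under either
    transient polarity, and even when transients occupy more than half
    the record. method "percentile" takes a stated lower percentile of
    the samples (exact for noiseless traces with positive transients);
    method "window" averages a stated pre-event time window at the start
    of the record.
    """

    method: str = "mode"
    percentile: float = 10.0
    window_s: float = 0.5

    def __post_init__(self):
        if self.method not in ("mode", "percentile", "window"):
            raise ValueError(
                "baseline method must be 'mode', 'percentile' or 'window'")
        if self.method == "percentile" and not 0 < self.percentile <= 50:
            raise ValueError("baseline percentile must lie in (0, 50]")
        if self.method == "window" and self.window_s <= 0:
            raise ValueError("baseline window must be positive")


def noise_sigma(values: np.ndarray) -> float:
    """Robust noise SD from first differences (MAD-based), insensitive to
    slow transients riding on the baseline."""
    d = np.diff(np.asarray(values, dtype=float))
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def density_mode(values: np.ndarray, sigma: float | None = None) -> float:
    """Mode of the sample distribution via a smoothed histogram.

    The histogram bin width is a quarter of the noise SD and the counts
    are smoothed with a Gaussian of one noise SD, so the densest cluster
    (the baseline) wins over broader transient-occupied value ranges. The
    peak position is refined by parabolic interpolation.
    """
    x = np.asarray(values, dtype=float)
    if sigma is None:
        sigma = noise_sigma(x)
    if sigma <= 0 or np.ptp(x) == 0:
        return float(np.median(x))
    bw = sigma / 4.0
    nbins = min(int(np.ceil(np.ptp(x) / bw)) + 1, 4096)
    counts, edges = np.histogram(x, bins=nbins)
    smooth = gaussian_filter1d(counts.astype(float), sigma=4.0, mode="nearest")
    k = int(np.argmax(smooth))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if 0 < k < nbins - 1:
        y0, y1, y2 = smooth[k - 1], smooth[k], smooth[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            k_frac = 0.5 * (y0 - y2) / denom
            return float(centers[k] + np.clip(k_frac, -0.5, 0.5)
                         * (centers[1] - centers[0]))
    return float(centers[k])


def estimate_f0(values: np.ndarray, baseline: BaselineDef | None = None,
                dt_ms: float | None = None) -> float:
    """Baseline fluorescence F0 of one channel (after any background removal)."""
    baseline = baseline or BaselineDef()
    values = np.asarray(values, dtype=float)
    if baseline.method == "mode":
        return density_mode(values)
    if baseline.method == "percentile":
        return float(np.percentile(values, baseline.percentile))
    if dt_ms is None:
        raise ValueError("window baseline requires dt_ms")
    n = max(1, int(round(baseline.window_s * 1000.0 / dt_ms)))
    return float(values[:n].mean())


def normalize_f0(values: np.ndarray, baseline: BaselineDef | None = None,
                 background: float = 0.0, dt_ms: float | None = None,
                 channel: str = "") -> np.ndarray:
    """F/F0: subtract the constant background, divide by the baseline.

    Scale-invariant (c*trace normalizes identically) and idempotent on an
    already-normalized trace up to baseline-estimation tolerance.
    """
    x = np.asarray(values, dtype=float) - background
    f0 = estimate_f0(x, baseline, dt_ms)
    if f0 <= 0:
        name = f" for channel {channel!r}" if channel else ""
        raise ValueError(f"nonpositive baseline F0{name}; "
                         "check background subtraction")
    return x / f0


def normalize_trace(trace: Trace, baseline: BaselineDef | None = None,
                    background: float | dict = 0.0) -> Trace:
    """Apply :func:`normalize_f0` to every channel of a trace."""
    rows = []
    for name in trace.channels:
        bg = background.get(name, 0.0) if isinstance(background, dict) else background
        rows.append(normalize_f0(trace.channel(name), baseline, bg,
                                 trace.dt_ms, channel=name))
    return Trace(np.vstack(rows), trace.dt_ms, trace.channels, dict(trace.roles),
                 extent_um=trace.extent_um)


def ratio_correct(sensor_ffo: np.ndarray, reference_ffo: np.ndarray) -> np.ndarray:
    """R/R0: pointwise sensor F/F0 divided by reference F/F0.

    Cancels common-mode optical artifacts (motion, defocus) shared by the
    two channels; a flat reference leaves the sensor signal unchanged.
    """
    s = np.asarray(sensor_ffo, dtype=float)
    r = np.asarray(reference_ffo, dtype=float)
    if s.shape != r.shape:
        raise ValueError("sensor and reference traces must have equal length")
    if np.any(r <= 0):
        raise ValueError("reference channel contains nonpositive samples")
    return s / r


def rolling_f0(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Frame-wise F/F0 by dividing each frame by a trailing moving average.

    The causal window (the current frame and the ``window - 1`` preceding
    ones; shorter at the start of the record) removes slow drift while
    leaving a constant series at exactly 1.0.
    """
    if window < 2:
        raise ValueError("window must be >= 2 frames")
    x = np.asarray(series, dtype=float)
    if x.size < window:
        raise ValueError("series shorter than the averaging window")
    avg = pd.Series(x).rolling(window, min_periods=1).mean().to_numpy()
    if np.any(avg <= 0):
        raise ValueError("moving-average baseline is nonpositive")
    return x / avg


def roi_mean(image: np.ndarray, roi: tuple, background: float = 0.0) -> float:
    """Mean background-subtracted intensity within a rectangular ROI.

    ``roi`` is (row_start, row_stop, col_start, col_stop) in pixels,
    half-open like numpy slices.
    """
    image = np.asarray(image, dtype=float)
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise ValueError("ROI is empty or outside the image bounds")
    return float(image[r0:r1, c0:c1].mean() - background)
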