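"""Sensor calibration: fluorescence -> absolute ATP concentration.

The single-site sensor obeys

    ATP = Kd * (F/Fmax - 1/Rf) / (1 - F/Fmax)

with Kd the apparent dissociation constant, Rf the dynamic range
(fluorescence ratio between the saturated and apo states) and Fmax the
fluorescence at saturating ATP, measured from a permeabilized preparation
superfused with 10 mM ATP. The default constants Kd = 1,460 µM and
Rf = 3.8 were determined in ventricular myocytes; applying them to nodal
tissue is an assumption recorded in output metadata.
"""

from __future__ import annotations

import warnings

import numpy as np

from .simgen import SensorModel, forward_sensor

__all__ = ["estimate_fmax", "atp_from_f", "saturation_fraction", "SensorModel"]


def saturation_fraction(sat_conc_uM: float, sensor: SensorModel) -> float:
    """F(c)/F(inf): how close a finite superfusion gets to true Fmax.

    10 mM ATP against Kd = 1.46 mM reaches only ~0.906 of the asymptotic
    fluorescence; dividing a measured plateau by this factor yields the
    corrected Fmax.
    """
    return float(forward_sensor(sat_conc_uM, sensor))


def estimate_fmax(
    saturating_values: np.ndarray,
    plateau_fraction: float = 0.5,
    max_cv: float = 0.10,
    saturation_correction: bool = False,
    sat_conc_uM: float = 10_000.0,
    sensor: SensorModel | None = None,
) -> float:
    """Fmax from a recording at saturating ATP: mean of the stable plateau.

    The plateau is the trailing ``plateau_fraction`` of the samples. A
    plateau coefficient of variation above ``max_cv`` raises, since an
    unstable plateau means the preparation had not equilibrated. With
    ``saturation_correction`` the finite superfusion concentration is
    compensated (divides by :func:`saturation_fraction`); the default is
    off, mirroring the plain plateau-mean procedure.
    """
    x = np.asarray(saturating_values, dtype=float)
    if x.size == 0:
        raise ValueError("empty saturating trace")
    tail = x[int(round(x.size * (1.0 - plateau_fraction))):]
    mean = float(tail.mean())
    if mean <= 0:
        raise ValueError("plateau mean is nonpositive")
    cv = float(tail.std() / mean)
    if cv > max_cv:
        raise ValueError(
            f"unstable plateau: CV {cv:.3f} exceeds {max_cv:.3f}")
    if saturation_correction:
        mean /= saturation_fraction(sat_conc_uM, sensor or SensorModel())
    return mean


def atp_from_f(
    f,
    sensor: SensorModel | None = None,
    fmax: float | None = None,
    clip_negative: bool = True,
):
    """Invert the calibration equation: fluorescence -> [ATP] in µM.

    Parameters
    ----------
    f : array-like
        Fluorescence in the same units as Fmax, or already normalized
        F/Fmax if ``fmax`` is 1.
    sensor : SensorModel
        Provides Kd, Rf and (unless ``fmax`` overrides it) Fmax.
    clip_negative : bool
        Fluorescence below the zero-ATP floor Fmax/Rf (noise) maps to a
        negative concentration; by default it is clipped to 0 µM with a
        warning. Strict mode (``clip_negative=False``) raises instead.

    Fluorescence at or above Fmax is outside the sensor's range and
    always raises (the equation diverges as F/Fmax -> 1).
    """
    sensor = sensor or SensorModel()
    fmax = sensor.fmax if fmax is None else fmax
    fn = np.asarray(f, dtype=float) / fmax
    scalar = fn.ndim == 0
    fn = np.atleast_1d(fn)
    if np.any(fn >= 1.0):
        raise ValueError("fluorescence at or above Fmax: sensor saturated")
    floor = 1.0 / sensor.rf
    below = fn < floor
    if np.any(below):
        if not clip_negative:
            raise ValueError(
                "fluorescence below the zero-ATP floor Fmax/Rf")
        warnings.warn(
            f"{int(below.sum())} sample(s) below the zero-ATP floor "
            "clipped to 0 µM", stacklevel=2)
    atp = sensor.kd_uM * (fn - floor) / (1.0 - fn)
    atp[below] = 0.0
    return float(atp[0]) if scalar else atp
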