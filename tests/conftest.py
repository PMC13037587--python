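import numpy as np
import pytest

from beatlock import (
    ArtifactSpec,
    BeatTrainSpec,
    SensorModel,
    TransientSpec,
    detect_events,
    generate_linescan,
    normalize_trace,
)
from beatlock.popstats import dip_null_distribution


@pytest.fixture(scope="session")
def sensor():
    """Default sensor constants (Kd 1,460 µM, Rf 3.8)."""
    return SensorModel()


@pytest.fixture(scope="session")
def superior_kinetics():
    """Transient shaped from the printed superior-region cytosolic kinetics."""
    return TransientSpec(amplitude=0.2, time_to_peak_ms=67.85,
                         decay_t_half_ms=20.55)


@pytest.fixture(scope="session")
def dip_null_300():
    """Bootstrap uniform null dips at n = 300, shared across dip tests."""
    return dip_null_distribution(300, n_boot=500, seed=7)


def detection_scores(seed, amplitude=0.1, noise_cv=0.05, frequency=3.5,
                     polarity=1, dt_ms=2.0):
    """(recall, precision) of the detector on one synthetic trace."""
    spec = TransientSpec(amplitude=amplitude, time_to_peak_ms=67.85,
                         decay_t_half_ms=20.55, polarity=polarity)
    trace, truth = generate_linescan(
        BeatTrainSpec(frequency_hz=frequency, record_duration_s=4.2),
        TransientSpec(0.5, 80, 40), spec,
        artifact=ArtifactSpec(noise_sd=noise_cv), dt_ms=dt_ms, seed=seed)
    ffo = normalize_trace(trace).by_role("sensor")
    events = [e for e in detect_events(ffo) if e.polarity == polarity]
    truth_on = truth.loc[truth.channel == "atp", "onset_s"].to_numpy() * 1000.0 / dt_ms
    det_on = np.array([e.onset_idx for e in events])
    tol = 50.0 / dt_ms  # 50 ms matching window
    if det_on.size == 0:
        return 0.0, 1.0
    recall = np.mean([np.any(np.abs(det_on - o) < tol) for o in truth_on])
    precision = np.mean([np.any(np.abs(truth_on - d) < tol) for d in det_on])
    return float(recall), float(precision)
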