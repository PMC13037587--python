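"""Per-event kinetics, signal mass and frequency conventions."""

import math

import numpy as np
import pytest

from beatlock import (
    ArtifactSpec,
    BeatTrainSpec,
    Event,
    TransientSpec,
    compute_kinetics,
    detect_events,
    event_frequency,
    generate_linescan,
    kernel_signal_mass,
    kinetics_table,
    max_sustainable_frequency,
    mean_interval_frequency,
    normalize_trace,
    signal_mass,
    signal_mass_rate,
    trace_summary,
    transient_kernel,
)


def _single_event_trace(spec, dt_ms=1.0, pad=200):
    """Noiseless F/F0 trace holding one kernel, plus its detected event."""
    k = transient_kernel(spec, dt_ms)
    ffo = np.ones(pad + k.size + pad)
    ffo[pad:pad + k.size] += k
    events = [e for e in detect_events(ffo) if e.polarity == spec.polarity]
    assert len(events) == 1
    return ffo, events[0]


class TestComputeKinetics:
    def test_superior_kinetics_recovered_within_one_sample(self, superior_kinetics):
        dt = 1.0
        ffo, ev = _single_event_trace(superior_kinetics, dt)
        rec = compute_kinetics(ev, ffo, dt)
        assert rec.time_to_peak_ms == pytest.approx(67.85, abs=dt)
        assert rec.decay_t_half_ms == pytest.approx(20.55, abs=dt)
        natural = 67.85 + math.log2(20) * 20.55
        assert rec.duration_ms == pytest.approx(natural, abs=2 * dt)
        assert rec.amplitude == pytest.approx(0.2, abs=0.002)

    def test_symmetric_triangle_t_half_is_half_descent(self):
        dt = 1.0
        tri = np.concatenate([np.linspace(0, 0.2, 51),
                              np.linspace(0.2, 0.0, 51)[1:]])
        ffo = np.concatenate([np.ones(50), 1 + tri, np.ones(50)])
        events = detect_events(ffo)
        rec = compute_kinetics(events[0], ffo, dt)
        # descending limb lasts 50 ms; half-amplitude is reached at 25 ms
        assert rec.decay_t_half_ms == pytest.approx(25.0, abs=1.0)

    def test_mode2_dip_polarity_symmetry(self, superior_kinetics):
        dt = 1.0
        dip = TransientSpec(0.2, 67.85, 20.55, polarity=-1)
        ffo_up, ev_up = _single_event_trace(superior_kinetics, dt)
        ffo_dn, ev_dn = _single_event_trace(dip, dt)
        up = compute_kinetics(ev_up, ffo_up, dt)
        dn = compute_kinetics(ev_dn, ffo_dn, dt)
        assert dn.time_to_peak_ms == pytest.approx(up.time_to_peak_ms, abs=1e-9)
        assert dn.decay_t_half_ms == pytest.approx(up.decay_t_half_ms, abs=1e-9)
        assert dn.signal_mass == pytest.approx(-up.signal_mass, abs=1e-9)

    def test_truncated_decay_flags_missing_t_half(self):
        ffo = np.concatenate([np.ones(30), 1 + np.linspace(0, 0.2, 40)])
        ev = Event(onset_idx=29, peak_idx=68, offset_idx=69, polarity=1,
                   amplitude=0.2, mean_ffo=1.1)
        rec = compute_kinetics(ev, ffo, 1.0)
        assert math.isnan(rec.decay_t_half_ms)
        assert "t_half_not_reached" in rec.flags

    def test_invalid_indices_rejected(self):
        ev = Event(onset_idx=0, peak_idx=5, offset_idx=20, polarity=1,
                   amplitude=0.1, mean_ffo=1.1)
        with pytest.raises(ValueError):
            compute_kinetics(ev, np.ones(10), 1.0)


class TestSignalMass:
    def test_rectangular_pulse_area(self):
        ffo = np.ones(300)
        ffo[100:201] = 1.1                      # height 0.1, width 100 ms
        ev = Event(onset_idx=100, peak_idx=150, offset_idx=200, polarity=1,
                   amplitude=0.1, mean_ffo=1.1)
        assert signal_mass(ev, ffo, dt_ms=1.0) == pytest.approx(10.0)

    def test_additivity_of_disjoint_events(self, superior_kinetics):
        dt = 1.0
        k = transient_kernel(superior_kinetics, dt)
        ffo = np.ones(1000)
        ffo[100:100 + k.size] += k
        ffo[600:600 + k.size] += k
        events = detect_events(ffo)
        masses = [signal_mass(e, ffo, dt) for e in events]
        assert len(masses) == 2
        assert sum(masses) == pytest.approx(2 * masses[0], rel=1e-9)

    def test_mode2_kernel_mass_matches_closed_form(self):
        spec = TransientSpec(0.23, 67.85, 20.55, polarity=-1)
        dt = 0.5
        ffo, ev = _single_event_trace(spec, dt)
        m = signal_mass(ev, ffo, dt)
        assert m < 0
        assert m == pytest.approx(kernel_signal_mass(spec), rel=0.005)

    def test_resampling_invariance(self, superior_kinetics):
        masses = []
        for dt in (1.0, 0.5):
            ffo, ev = _single_event_trace(superior_kinetics, dt)
            masses.append(signal_mass(ev, ffo, dt))
        assert masses[1] == pytest.approx(masses[0], rel=0.01)

    def test_extent_scaling(self):
        ffo = np.ones(50)
        ffo[10:31] = 1.1
        ev = Event(onset_idx=10, peak_idx=20, offset_idx=30, polarity=1,
                   amplitude=0.1, mean_ffo=1.1)
        assert signal_mass(ev, ffo, 1.0, extent_um=7.0) == pytest.approx(
            7.0 * signal_mass(ev, ffo, 1.0))


class TestRatesAndFrequency:
    def test_printed_rate_arithmetic(self):
        # a per-trace total of 895.70 AU over the 4.2 s record
        assert signal_mass_rate([895.70], 4.2) == pytest.approx(213.26, abs=0.01)

    def test_rate_zero_and_scaling(self):
        assert signal_mass_rate([], 4.2) == 0.0
        assert signal_mass_rate([10.0, 5.0], 8.4) == pytest.approx(
            signal_mass_rate([10.0, 5.0], 4.2) / 2.0)

    def test_rate_times_duration_identity(self):
        masses = [3.0, 4.5, -1.0]
        assert signal_mass_rate(masses, 3.7) * 3.7 == pytest.approx(sum(masses))

    def test_event_frequency(self):
        assert event_frequency(16, 4.0) == 4.0
        assert event_frequency(0, 4.0) == 0.0
        with pytest.raises(ValueError):
            event_frequency(3, 0.0)

    def test_simgen_frequency_recovery(self):
        trace, truth = generate_linescan(
            BeatTrainSpec(frequency_hz=2.6, record_duration_s=10.0),
            TransientSpec(0.5, 80, 40), TransientSpec(0.2, 67.85, 20.55),
            artifact=ArtifactSpec(noise_sd=0.02), seed=0)
        ffo = normalize_trace(trace).by_role("sensor")
        n = sum(e.polarity == 1 for e in detect_events(ffo))
        assert event_frequency(n, 10.0) == pytest.approx(2.6, abs=0.1)

    def test_mean_interval_convention(self):
        evs = [Event(onset_idx=i * 100, peak_idx=i * 100 + 10,
                     offset_idx=i * 100 + 50, polarity=1, amplitude=0.1,
                     mean_ffo=1.1) for i in range(5)]
        assert mean_interval_frequency(evs, dt_ms=2.0) == pytest.approx(5.0)
        assert math.isnan(mean_interval_frequency(evs[:1], 2.0))

    def test_max_sustainable_frequency_printed_bounds(self):
        assert max_sustainable_frequency(240.0) == pytest.approx(4.2, abs=0.05)
        assert max_sustainable_frequency(282.0) == pytest.approx(3.5, abs=0.05)
        assert max_sustainable_frequency(1000.0) == 1.0
        with pytest.raises(ValueError):
            max_sustainable_frequency(0.0)


def test_tables_and_summary(superior_kinetics):
    dt = 1.0
    ffo, ev = _single_event_trace(superior_kinetics, dt)
    rec = compute_kinetics(ev, ffo, dt)
    df = kinetics_table([rec])
    assert list(df.columns)[:4] == ["event_id", "polarity", "amplitude",
                                    "time_to_peak_ms"]
    summary = trace_summary([rec], record_duration_s=1.0)
    assert summary["n_events"] == 1 and summary["n_mode1"] == 1
    assert summary["signal_mass_rate_au_per_s"] == pytest.approx(
        rec.signal_mass)


class TestBeatAverage:
    @staticmethod
    def _paced_trace(noise_sd, seed, common_mode=0.05):
        trace, _ = generate_linescan(
            BeatTrainSpec(frequency_hz=3.5, record_duration_s=4.2),
            TransientSpec(0.5, 80.0, 40.0),
            TransientSpec(0.2, 67.85, 20.55),
            artifact=ArtifactSpec(common_mode_amplitude=common_mode,
                                  noise_sd=noise_sd), seed=seed)
        from beatlock import normalize_f0, ratio_correct
        norm = normalize_trace(trace)
        rr = normalize_f0(ratio_correct(norm.by_role("sensor"),
                                        norm.by_role("reference")))
        events = [e for e in detect_events(rr) if e.polarity == 1]
        return rr, events, trace.dt_ms

    def test_noiseless_average_matches_kernel(self):
        from beatlock import averaged_kinetics
        rr, events, dt = self._paced_trace(0.0, seed=0)
        rec = averaged_kinetics(rr, events, dt)
        assert rec.decay_t_half_ms == pytest.approx(20.55, abs=dt)
        assert rec.time_to_peak_ms == pytest.approx(67.85, abs=2 * dt)
        assert rec.amplitude == pytest.approx(0.2, abs=0.005)

    def test_noisy_average_less_biased_than_single_events(self):
        from beatlock import averaged_kinetics
        averaged, singles = [], []
        for seed in range(5):
            rr, events, dt = self._paced_trace(0.01, seed=seed)
            averaged.append(averaged_kinetics(rr, events, dt).decay_t_half_ms)
            singles += [compute_kinetics(e, rr, dt).decay_t_half_ms
                        for e in events]
        assert np.mean(averaged) == pytest.approx(20.55, rel=0.15)
        # the mean single-event reading sits farther from the truth
        assert (abs(np.mean(averaged) - 20.55)
                < abs(np.nanmean(singles) - 20.55))

    def test_validation(self):
        from beatlock import beat_average
        with pytest.raises(ValueError):
            beat_average(np.ones(100), [])
        rr, events, dt = self._paced_trace(0.0, seed=1)
        flipped = Event(events[0].onset_idx, events[0].peak_idx,
                        events[0].offset_idx, -1, events[0].amplitude,
                        events[0].mean_ffo)
        with pytest.raises(ValueError, match="polarity"):
            beat_average(rr, [events[1], flipped])
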