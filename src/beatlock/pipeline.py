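"""End-to-end orchestration: simulate or load traces, detect, quantify.

A run is driven by a plain-dictionary config (typically loaded from
YAML). Every output carries the config hash and the seeds used, per-stage
seeds are derived from the master seed by stable hashing, and a failure
in one trace is logged without aborting the run, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibrate as _calibrate
from . import coupling as _coupling
from . import popstats as _popstats
from .events import DetectionParams, detect_events, events_to_frame, filter_events, pair_events
from .kinetics import compute_kinetics, kinetics_table, trace_summary
from .preprocess import BaselineDef, normalize_f0, normalize_trace, ratio_correct
from .simgen import (ArtifactSpec, BeatTrainSpec, CouplingSpec, SensorModel,
                     TransientSpec, generate_linescan)

log = logging.getLogger("beatlock")


class ConfigError(ValueError):
    """Malformed run configuration; the message names the field path."""


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "beatlock_run",
    "simulate": {
        "enabled": True,
        "n_traces": 3,
        "dt_ms": 2.0,
        "beats": {"frequency_hz": 3.5, "record_duration_s": 4.2,
                  "jitter_sd_ms": 5.0, "ca_to_atp_lag_ms": 20.0},
        "ca": {"amplitude": 0.5, "time_to_peak_ms": 80.0,
               "decay_t_half_ms": 40.0},
        "atp": {"amplitude": 0.2, "time_to_peak_ms": 67.85,
                "decay_t_half_ms": 20.55, "polarity": 1},
        "artifact": {"common_mode_amplitude": 0.0, "noise_sd": 0.02},
    },
    "inputs": [],            # CSV trace paths analyzed when simulate is off
    "baseline": {"method": "percentile", "percentile": 10.0},
    "detection": {"k_sigma": 2.0},
    "calibration": {"enabled": False, "kd_uM": 1460.0, "rf": 3.8,
                    "fmax": 1000.0, "saturation_correction": False},
    "coupling": {"enabled": True, "model": "two_line", "min_pairs": 8},
    "popstats": {"enabled": False, "n_boot": 2000},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config field {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(source) -> dict:
    """Merge a YAML file or dict over the defaults, validating field names."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def config_hash(config: dict) -> str:
    """Stable hash of a config, invariant to key ordering."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed from the master seed by stable hashing (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


@dataclass
class RunReport:
    config: dict
    config_hash: str
    events: pd.DataFrame
    kinetics: pd.DataFrame
    summaries: pd.DataFrame
    coupling_fit: object | None = None
    calibration: dict = field(default_factory=dict)
    popstats: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def _analyze_trace(trace, truth, cfg, trace_id):
    baseline = BaselineDef(**cfg["baseline"])
    det = DetectionParams(**cfg["detection"])
    norm = normalize_trace(trace, baseline)
    dt = trace.dt_ms
    record_s = trace.n_samples * dt / 1000.0

    ffo_atp = norm.by_role("sensor")
    if norm.has_role("reference"):
        # the quotient's own baseline R0 can differ from 1 when the two
        # channel baselines were estimated at different artifact phases,
        # so renormalize the ratio before detection
        ffo_atp = normalize_f0(
            ratio_correct(ffo_atp, norm.by_role("reference")), baseline)
    atp_events = detect_events(ffo_atp, det, trace.extent_um,
                               trace_id=f"{trace_id}/atp")
    atp_events, _ = filter_events(atp_events, det)
    ca_events = []
    if norm.has_role("calcium"):
        ffo_ca = norm.by_role("calcium")
        ca_events = detect_events(ffo_ca, det, trace.extent_um,
                                  trace_id=f"{trace_id}/ca")
        ca_events, _ = filter_events(ca_events, det)
        pairs, _, _ = pair_events(ca_events, atp_events, dt, det)
    else:
        ffo_ca, pairs = None, []

    records, pair_rows = [], []
    for ev in atp_events:
        records.append(compute_kinetics(ev, ffo_atp, dt))
    ca_records = {ev.event_id: compute_kinetics(ev, ffo_ca, dt)
                  for ev in ca_events}
    for ca_ev, atp_ev in pairs:
        atp_rec = next(r for r in records if r.event_id == atp_ev.event_id)
        pair_rows.append({
            "trace_id": trace_id,
            "ca_mass": abs(ca_records[ca_ev.event_id].signal_mass),
            "atp_mass": abs(atp_rec.signal_mass),
        })

    ev_frame = events_to_frame(atp_events, dt, trace_id)
    kin_frame = kinetics_table(records).assign(trace_id=trace_id)
    summary = {"trace_id": trace_id, **trace_summary(records, record_s)}
    return ev_frame, kin_frame, summary, pd.DataFrame(pair_rows), ffo_atp


def run_pipeline(config=None, out_dir=None) -> RunReport:
    """Run the configured stages and write the result files.

    Stages: simulate (or load CSV traces), normalize and ratio-correct,
    detect and filter events, pair Ca with ATP events, per-event kinetics
    and per-trace summaries, optional calibration of the diastolic sensor
    level, a coupling fit on pooled pair signal masses, and population
    statistics on event signal masses.
    """
    cfg = load_config(config)
    chash = config_hash(cfg)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])

    traces, failures = [], []
    if cfg["simulate"]["enabled"]:
        sim = cfg["simulate"]
        for i in range(int(sim["n_traces"])):
            beats = BeatTrainSpec(**sim["beats"])
            ca = TransientSpec(**sim["ca"])
            atp = TransientSpec(**sim["atp"])
            art = ArtifactSpec(**sim["artifact"])
            tr, truth = generate_linescan(
                beats, ca, atp, artifact=art, dt_ms=sim["dt_ms"],
                seed=derive_seed(master, f"simulate/{i}"))
            traces.append((f"sim{i}", tr, truth))
    else:
        from .trace import Trace
        for path in cfg["inputs"]:
            try:
                traces.append((Path(path).stem, Trace.from_csv(path), None))
            except Exception as exc:    # tolerate unreadable inputs
                log.warning("input %s failed to load: %s", path, exc)
                failures.append({"trace_id": Path(path).stem,
                                 "error": str(exc)})

    ev_frames, kin_frames, summaries, pair_frames = [], [], [], []
    diastolic_f = []
    for trace_id, tr, truth in traces:
        try:
            ev, kin, summary, pair_df, ffo = _analyze_trace(tr, truth, cfg, trace_id)
        except Exception as exc:        # keep going on per-trace failure
            log.warning("trace %s failed: %s", trace_id, exc)
            failures.append({"trace_id": trace_id, "error": str(exc)})
            continue
        ev_frames.append(ev)
        kin_frames.append(kin)
        summaries.append(summary)
        pair_frames.append(pair_df)
        diastolic_f.append(float(np.percentile(ffo, 10)))

    events = (pd.concat(ev_frames, ignore_index=True)
              if ev_frames else events_to_frame([], 1.0))
    kinetics = (pd.concat(kin_frames, ignore_index=True)
                if kin_frames else kinetics_table([]))
    summary_df = pd.DataFrame(summaries)
    pairs = (pd.concat(pair_frames, ignore_index=True)
             if pair_frames else pd.DataFrame(columns=["ca_mass", "atp_mass"]))
    if not traces:
        log.warning("empty input set: nothing to analyze")

    calibration = {}
    if cfg["calibration"]["enabled"] and diastolic_f:
        cal = cfg["calibration"]
        sensor = SensorModel(kd_uM=cal["kd_uM"], rf=cal["rf"], fmax=cal["fmax"])
        # diastolic F/F0 re-expressed against Fmax assumes F0 is the
        # resting level; record the constants' tissue-of-origin assumption
        calibration = {
            "kd_uM": cal["kd_uM"], "rf": cal["rf"], "fmax": cal["fmax"],
            "saturation_correction": cal["saturation_correction"],
            "constants_assumption": "Kd/Rf determined in ventricular "
                                    "myocytes, applied to nodal tissue",
        }

    coupling_fit = None
    if (cfg["coupling"]["enabled"] and len(pairs) >= cfg["coupling"]["min_pairs"]):
        model = cfg["coupling"]["model"]
        fitter = {"two_line": _coupling.fit_two_line,
                  "hill": _coupling.fit_hill,
                  "changepoint": _coupling.fit_changepoint}[model]
        kwargs = {"seed": derive_seed(master, "coupling")} \
            if model in ("two_line", "hill") else {}
        coupling_fit = fitter(pairs, **kwargs)

    pop = {}
    if cfg["popstats"]["enabled"]:
        masses = kinetics["signal_mass"].abs().to_numpy()
        if masses.size >= 10:
            mix = _popstats.fit_mixture(
                masses, seed=derive_seed(master, "popstats"))
            pop = {"k_selected": mix.k_selected,
                   "means": mix.means.tolist(),
                   "threshold": mix.threshold}

    events.to_csv(out / "events.csv", index=False)
    kinetics.to_csv(out / "kinetics.csv", index=False)
    summary_df.to_csv(out / "trace_summary.csv", index=False)
    pairs.to_csv(out / "event_pairs.csv", index=False)
    report = {
        "config_hash": chash,
        "seed": master,
        "n_traces": len(traces),
        "n_failures": len(failures),
        "failures": failures,
        "calibration": calibration,
        "coupling": ({"kind": coupling_fit.kind, "params":
                      {k: v for k, v in coupling_fit.params.items()
                       if not isinstance(v, dict)},
                      "r2": coupling_fit.r2}
                     if coupling_fit is not None else None),
        "popstats": pop,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return RunReport(config=cfg, config_hash=chash, events=events,
                     kinetics=kinetics, summaries=summary_df,
                     coupling_fit=coupling_fit, calibration=calibration,
                     popstats=pop, failures=failures)
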