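"""Readers/writers for the on-disk formats, run configuration and the
end-to-end pipeline runner.

Continuous recordings are little-endian int16 flat binary (interleaved
frames: all channels of sample 0, then sample 1, …) with a JSON sidecar
``{sampling_rate_hz, n_channels, uv_per_bit, channel_meta[]}``.  Events are
CSV with header ``time_s,trial_type,response_time_s``.  Sorted units and TF
tensors go to HDF5.  Every output directory carries a provenance record
(config hash, version, input checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lfp import TFParams, session_icc, session_tf_pipeline
from .qc import QCCriteria, evaluate_units, session_yield_efficiency
from .sorting import ClusterParams, DetectionParams, sort_recording
from .synthetic import generate_lfp_session, simulate_spike_session
from .types import (
    ChannelMeta,
    ContinuousRecording,
    EventTable,
    GroundTruth,
    OscillationSpec,
    SimulationSpec,
    TFTensor,
    UnitCluster,
    UnitMetrics,
)

log = logging.getLogger(__name__)

EVENT_COLUMNS = ["time_s", "trial_type", "response_time_s"]


# ---------------------------------------------------------------- recordings

def write_recording(
    recording: ContinuousRecording, path: str | Path, uv_per_bit: float = 0.1
) -> Path:
    """Write int16 flat binary + JSON sidecar; returns the binary path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    q = np.clip(np.round(recording.data / uv_per_bit), -32768, 32767).astype("<i2")
    q.tofile(path)
    sidecar = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "n_channels": recording.n_channels,
        "uv_per_bit": uv_per_bit,
        "dtype": "int16",
        "channel_meta": [m.to_dict() for m in recording.channel_meta],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path, mmap: bool = True) -> ContinuousRecording:
    """Read a flat-binary recording via its JSON sidecar.

    With ``mmap=True`` samples are memory-mapped, so callers can stream
    without loading the whole file; voltages are dequantized lazily on
    first arithmetic use.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("dtype", "int16") != "int16":
        raise ValueError(f"unknown dtype {sidecar.get('dtype')!r}")
    n_ch = int(sidecar["n_channels"])
    n_bytes = path.stat().st_size
    if n_bytes % (2 * n_ch):
        raise ValueError(
            f"binary size {n_bytes} B is not a whole number of {n_ch}-channel "
            f"int16 frames (expected multiple of {2 * n_ch} B)"
        )
    n_frames = n_bytes // (2 * n_ch)
    raw = np.memmap(path, dtype="<i2", mode="r", shape=(n_frames, n_ch)) if mmap else \
        np.fromfile(path, dtype="<i2").reshape(n_frames, n_ch)
    data = np.asarray(raw, dtype=float) * float(sidecar["uv_per_bit"])
    meta = [ChannelMeta.from_dict(d) for d in sidecar["channel_meta"]]
    return ContinuousRecording(
        data=data, sampling_rate_hz=float(sidecar["sampling_rate_hz"]), channel_meta=meta
    )


# -------------------------------------------------------------------- events

def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.frame.to_csv(path, index=False, columns=EVENT_COLUMNS)
    return path


def read_events(path: str | Path) -> EventTable:
    """Read the behavioral event CSV; times must be ascending."""
    frame = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"event CSV missing columns {sorted(missing)}")
    frame["trial_type"] = frame["trial_type"].astype(str)
    return EventTable(frame=frame)


# -------------------------------------------------------------- ground truth

def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "spike_times_per_unit": {str(k): v.tolist() for k, v in gt.spike_times_per_unit.items()},
        "templates": [
            {
                "unit_id": t.unit_id,
                "waveform": t.waveform.tolist(),
                "class_label": t.class_label,
                "channel_gains": t.channel_gains.tolist(),
                "bundle": t.bundle,
                "width_ms": t.width_ms,
                "hyperpolarization_ms": t.hyperpolarization_ms,
            }
            for t in gt.templates
        ],
        "artifact_trials": np.asarray(gt.artifact_trials).tolist(),
        "oscillations": [asdict(o) for o in gt.oscillations],
        "session_effects": gt.session_effects,
        "dropped_spikes": gt.dropped_spikes,
    }
    path.write_text(json.dumps(payload))
    return path


# ------------------------------------------------------------- units / HDF5

def write_units_h5(
    clusters: list[UnitCluster], path: str | Path, sampling_rate_hz: float
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate_hz"] = sampling_rate_hz
        for c in clusters:
            g = f.create_group(f"unit_{c.cluster_id:04d}")
            g.attrs.update(
                cluster_id=c.cluster_id, group=c.group, best_channel=c.best_channel
            )
            g.create_dataset("spike_times_s", data=c.spike_times_s, track_times=False)
            g.create_dataset("spike_samples", data=c.spike_samples, track_times=False)
            g.create_dataset("mean_waveform", data=c.mean_waveform, track_times=False)
            g.create_dataset("features", data=c.features, track_times=False)
    return path


def read_units_h5(path: str | Path) -> tuple[list[UnitCluster], float]:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate_hz"])
        clusters = [
            UnitCluster(
                cluster_id=int(g.attrs["cluster_id"]),
                spike_times_s=g["spike_times_s"][:],
                spike_samples=g["spike_samples"][:],
                mean_waveform=g["mean_waveform"][:],
                features=g["features"][:],
                group=int(g.attrs["group"]),
                best_channel=int(g.attrs["best_channel"]),
            )
            for g in (f[k] for k in sorted(f.keys()))
        ]
    return clusters, fs


def write_spike_times_csv(clusters: list[UnitCluster], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"unit_id": c.cluster_id, "time_s": t} for c in clusters for t in c.spike_times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(path, index=False)
    return path


def write_metrics_csv(metrics: list[UnitMetrics], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "unit_id": m.unit_id,
                "rate_hz": m.firing_rate_hz,
                "isi_frac": m.isi_violation_frac,
                "snr": m.snr,
                "width_ms": m.peak_to_trough_width_ms,
                "hyper_ms": m.hyperpolarization_ms,
                "class": m.ei_class,
                "accepted": m.accepted,
            }
            for m in metrics
        ]
    ).to_csv(path, index=False)
    return path


def write_tf_h5(tensors: dict[str, TFTensor], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for name, tf in tensors.items():
            g = f.create_group(name)
            g.attrs["state"] = tf.state
            g.attrs["dims"] = "time,frequency,electrode" if not tf.per_trial else \
                "trial,time,frequency,electrode"
            g.create_dataset("data", data=tf.data, track_times=False)
            g.create_dataset("times_s", data=tf.times_s, track_times=False)
            g.create_dataset("freqs_hz", data=tf.freqs_hz, track_times=False)
    return path


def read_tf_h5(path: str | Path) -> dict[str, TFTensor]:
    out: dict[str, TFTensor] = {}
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            out[name] = TFTensor(
                data=g["data"][:],
                times_s=g["times_s"][:],
                freqs_hz=g["freqs_hz"][:],
                state=g.attrs["state"],
            )
    return out


# --------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """One YAML file governs a run; CLI flags override its fields."""

    out_dir: str = "ephysforge_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate", "sort", "qc", "lfp", "icc"])
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    qc: QCCriteria = field(default_factory=QCCriteria)
    tf: TFParams = field(default_factory=TFParams)
    n_lfp_trials: int = 60
    n_icc_sessions: int = 4
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        nested = {
            "simulation": SimulationSpec,
            "detection": DetectionParams,
            "clustering": ClusterParams,
            "qc": QCCriteria,
            "tf": TFParams,
        }
        kwargs = {}
        for k, v in raw.items():
            if k in nested and isinstance(v, dict):
                for tup in ("baseline_window_s", "display_band_hz"):
                    if tup in v:
                        v[tup] = tuple(v[tup])
                if "unit_rates_hz" in v:
                    v["unit_rates_hz"] = tuple(v["unit_rates_hz"])
                kwargs[k] = nested[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(out_dir: Path, config: RunConfig, inputs: dict[str, Path]) -> Path:
    record = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        "input_checksums": {
            k: hashlib.sha256(Path(p).read_bytes()).hexdigest() for k, p in inputs.items()
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=1))
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages (simulate → sort → qc → lfp → icc).

    All randomness flows from ``config.seed``; re-running with the same
    config reproduces every numeric output bit-for-bit (the provenance
    record alone carries a timestamp).  Returns a summary dict.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    inputs: dict[str, Path] = {}

    sim = config.simulation
    sim = SimulationSpec(**{**sim.__dict__, "seed": config.seed})
    rec = gt = None
    stage = "?"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            rec, gt = simulate_spike_session(sim, units_per_bundle=5)
            rec_path = write_recording(rec, out / "spikes.bin")
            write_ground_truth(gt, out / "spikes_truth.json")
            inputs["spikes.bin"] = rec_path
            summary["stages"]["simulate"] = {
                "n_units": len(gt.templates),
                "n_spikes": int(sum(len(v) for v in gt.spike_times_per_unit.values())),
            }
        if "sort" in config.stages:
            stage = "sort"
            if rec is None:
                rec = read_recording(out / "spikes.bin")
            cp = ClusterParams(**{**config.clustering.__dict__, "seed": config.seed})
            clusters, referenced, _ = sort_recording(rec, config.detection, cp)
            write_units_h5(clusters, out / "units.h5", rec.sampling_rate_hz)
            write_spike_times_csv(clusters, out / "spike_times.csv")
            summary["stages"]["sort"] = {"n_clusters": len(clusters)}
            summary["_clusters"], summary["_referenced"] = clusters, referenced
        if "qc" in config.stages:
            stage = "qc"
            clusters, referenced = summary.pop("_clusters"), summary.pop("_referenced")
            pre, post = config.detection.snippet_samples(rec.sampling_rate_hz)
            metrics = evaluate_units(
                clusters,
                referenced.data,
                rec.sampling_rate_hz,
                rec.duration_s,
                config.qc,
                snippet_pre=pre,
                snippet_post=post,
                seed=config.seed,
            )
            write_metrics_csv(metrics, out / "unit_metrics.csv")
            accepted = [m for m in metrics if m.accepted]
            ses = session_yield_efficiency(accepted, n_sites=32 if sim.n_channels <= 32 else 64)
            (out / "session_summary.json").write_text(
                json.dumps(
                    {
                        "session_id": ses.session_id,
                        "yield_per_region": ses.yield_per_region,
                        "efficiency": ses.efficiency,
                        "n_recording_sites": ses.n_recording_sites,
                        "n_accepted": ses.n_accepted,
                    },
                    indent=1,
                )
            )
            summary["stages"]["qc"] = {
                "n_accepted": ses.n_accepted,
                "efficiency": ses.efficiency,
            }
        if "lfp" in config.stages or "icc" in config.stages:
            stage = "lfp"
            lfp_spec = SimulationSpec(
                n_channels=32,
                sampling_rate_hz=1000.0,
                noise_sd_uv=20.0,
                common_mode_amplitude_uv=30.0,
                artifact_trial_fraction=0.05,
                seed=config.seed + 1,
            )
            osc = [
                OscillationSpec(
                    electrodes=range(14, 22), band="beta", center_hz=20.0,
                    onset_s=0.2, offset_s=0.8, amplitude_uv=40.0, trial_types=("go",),
                ),
                OscillationSpec(
                    electrodes=range(0, 8), band="theta", center_hz=6.0,
                    onset_s=0.0, offset_s=1.0, amplitude_uv=40.0,
                ),
            ]
            lfp_rec, events, lfp_gt = generate_lfp_session(
                lfp_spec, osc, n_trials=config.n_lfp_trials
            )
            write_events(events, out / "events.csv")
            if "lfp" in config.stages:
                by_type, rejected = session_tf_pipeline(lfp_rec, events, config.tf)
                write_tf_h5(by_type, out / "tf.h5")
                pd.DataFrame(
                    {"trial": np.arange(len(rejected)), "rejected": rejected.astype(int)}
                ).to_csv(out / "rejected_trials.csv", index=False)
                summary["stages"]["lfp"] = {
                    "n_rejected": int(rejected.sum()),
                    "trial_types": sorted(by_type),
                }
        if "icc" in config.stages:
            stage = "icc"
            tensors = []
            for s in range(config.n_icc_sessions):
                spec_s = SimulationSpec(**{**lfp_spec.__dict__, "seed": config.seed + 10 + s})
                rec_s, ev_s, _ = generate_lfp_session(spec_s, osc, n_trials=config.n_lfp_trials)
                by_type_s, _ = session_tf_pipeline(rec_s, ev_s, config.tf)
                key = sorted(by_type_s)[0]
                tensors.append(by_type_s[key])
            icc = session_icc(tensors)
            pd.DataFrame(
                {
                    "electrode": np.arange(len(icc.icc)),
                    "icc": icc.icc,
                    "n_sessions": icc.n_sessions,
                }
            ).to_csv(out / "icc.csv", index=False)
            summary["stages"]["icc"] = {"median_icc": float(np.median(icc.icc))}
    except Exception as exc:                                   # noqa: BLE001
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    summary.pop("_clusters", None)
    summary.pop("_referenced", None)
    write_provenance(out, config, inputs)
    return summary
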