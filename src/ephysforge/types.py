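"""Core in-memory containers shared across the simulation, sorting, QC and LFP stages.

Conventions: voltages are microvolts (µV), times are seconds, sample indices
are 0-based.  A *polytrode group* is the fixed set of 16 wires (two cannula
bundles) that are referenced and clustered together.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"
OUTLIER = "outlier"


@dataclass
class ChannelMeta:
    """Per-wire metadata carried in the recording sidecar."""

    index: int
    bundle: int                      # 16-channel polytrode group id
    region: str = "unknown"
    impedance_mohm: float | None = None
    broken: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMeta":
        return cls(**d)


@dataclass
class ContinuousRecording:
    """samples × channels voltage matrix with sampling rate and channel metadata."""

    data: np.ndarray                 # (n_samples, n_channels) float, µV
    sampling_rate_hz: float
    channel_meta: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (samples × channels)")
        if self.data.shape[1] != len(self.channel_meta):
            raise ValueError(
                f"channel_meta length {len(self.channel_meta)} does not match "
                f"{self.data.shape[1]} data columns"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def bundle_map(self) -> np.ndarray:
        return np.array([m.bundle for m in self.channel_meta])

    def bundle_channels(self, bundle: int) -> np.ndarray:
        return np.flatnonzero(self.bundle_map == bundle)


@dataclass
class SpikeTemplate:
    """Ground-truth spike waveform with per-channel attenuation within one bundle.

    ``channel_gains`` covers the template's 16-channel bundle; the maximum
    gain is 1 on the wire nearest the cell.
    """

    unit_id: int
    waveform: np.ndarray             # (snippet_len,) µV on the best channel
    class_label: str                 # excitatory | inhibitory
    channel_gains: np.ndarray        # (bundle_size,) in [0, 1], max == 1
    bundle: int = 0
    width_ms: float | None = None                  # planted peak-to-trough width
    hyperpolarization_ms: float | None = None      # planted AHP duration

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if np.ptp(self.waveform) <= 0:
            raise ValueError("template waveform must have positive peak-to-peak")
        if not np.isclose(self.channel_gains.max(), 1.0):
            raise ValueError("maximum channel gain must be 1")

    @property
    def peak_to_peak_uv(self) -> float:
        return float(np.ptp(self.waveform))


@dataclass
class SimulationSpec:
    """Parameters for one synthetic recording session."""

    n_channels: int = 32
    sampling_rate_hz: float = 25_000.0
    duration_s: float = 60.0
    unit_rates_hz: Sequence[float] = (5.0,)
    refractory_ms: float = 3.0
    noise_sd_uv: float = 10.0
    common_mode_amplitude_uv: float = 0.0
    artifact_trial_fraction: float = 0.0
    event_mix: dict[str, float] = field(default_factory=lambda: {"wait": 0.75, "go": 0.25})
    bundle_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.unit_rates_hz):
            raise ValueError("unit rates must be > 0")
        if self.refractory_ms < 1:
            raise ValueError("refractory_ms must be >= 1")
        if not 0 <= self.artifact_trial_fraction <= 1:
            raise ValueError("artifact_trial_fraction must be in [0, 1]")
        if self.event_mix and abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_mix proportions must sum to 1")

    @property
    def bundle_map(self) -> np.ndarray:
        return np.arange(self.n_channels) // self.bundle_size


@dataclass
class OscillationSpec:
    """One planted event-locked oscillatory burst."""

    electrodes: Sequence[int]
    band: str
    center_hz: float
    onset_s: float                   # relative to locking event
    offset_s: float
    amplitude_uv: float
    trial_types: Sequence[str] | None = None   # None = every trial


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream validation."""

    spike_times_per_unit: dict[int, np.ndarray] = field(default_factory=dict)
    templates: list[SpikeTemplate] = field(default_factory=list)
    artifact_trials: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    oscillations: list[OscillationSpec] = field(default_factory=list)
    session_effects: list[dict] = field(default_factory=list)
    dropped_spikes: int = 0


@dataclass
class SpikeEvent:
    """One detected threshold crossing, merged across the polytrode group."""

    sample: int
    channel: int                     # largest-amplitude channel
    amplitude_uv: float


@dataclass
class SpikeEventSet:
    """Detected events of one polytrode group with aligned multi-channel snippets."""

    group: int
    events: list[SpikeEvent]
    snippets: np.ndarray             # (n_events, snippet_len, n_group_channels)
    group_channels: np.ndarray       # channel indices forming the concat order
    sampling_rate_hz: float

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([e.sample for e in self.events]) / self.sampling_rate_hz

    def concatenated(self) -> np.ndarray:
        """Events × (snippet_len · n_channels): channel-wise concatenated shapes."""
        n, t, c = self.snippets.shape
        return self.snippets.transpose(0, 2, 1).reshape(n, t * c)


@dataclass
class UnitCluster:
    """One sorted cluster: member spikes plus summary waveforms and features."""

    cluster_id: int
    spike_times_s: np.ndarray
    spike_samples: np.ndarray
    mean_waveform: np.ndarray        # (snippet_len, n_group_channels)
    features: np.ndarray             # (n_members, n_features)
    group: int
    best_channel: int                # channel of largest mean-waveform p2p (global index)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)


@dataclass
class UnitMetrics:
    """Quality metrics and acceptance verdict for one sorted unit."""

    unit_id: int
    firing_rate_hz: float
    isi_violation_frac: float
    snr: float
    peak_to_trough_width_ms: float = float("nan")
    hyperpolarization_ms: float = float("nan")
    ei_class: str = OUTLIER
    accepted: bool = False
    failed_criteria: list[str] = field(default_factory=list)
    region: str = "unknown"


@dataclass
class SessionSummary:
    session_id: str
    yield_per_region: dict[str, int]
    efficiency: float
    n_recording_sites: int
    n_accepted: int


@dataclass
class EventTable:
    """Behavioral events: onset time, trial type, response time."""

    frame: pd.DataFrame              # columns time_s, trial_type, response_time_s

    def __post_init__(self) -> None:
        required = {"time_s", "trial_type", "response_time_s"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        t = self.frame["time_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError("event times must be ascending")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def times_s(self) -> np.ndarray:
        return self.frame["time_s"].to_numpy(dtype=float)

    @property
    def trial_types(self) -> np.ndarray:
        return self.frame["trial_type"].to_numpy()


@dataclass
class EpochedLFP:
    """trial × time × electrode tensor cut around behavioral events."""

    data: np.ndarray                 # (n_trials, n_times, n_electrodes) µV
    times_s: np.ndarray              # relative to locking event
    trial_labels: np.ndarray
    sampling_rate_hz: float
    rejected: np.ndarray | None = None   # boolean, True = artifact trial
    referenced: bool = False

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[2]

    def kept_mask(self) -> np.ndarray:
        if self.rejected is None:
            return np.ones(self.n_trials, dtype=bool)
        return ~self.rejected


STATE_RAW = "raw"
STATE_BASELINED = "baseline-subtracted"
STATE_ZSCORED = "z-scored"


@dataclass
class TFTensor:
    """Morlet amplitude tensor.

    ``data`` is (trials, times, freqs, electrodes) when per-trial, or
    (times, freqs, electrodes) once averaged.  Edge samples without full
    wavelet support are NaN.
    """

    data: np.ndarray
    times_s: np.ndarray
    freqs_hz: np.ndarray
    state: str = STATE_RAW
    trial_labels: np.ndarray | None = None
    degenerate_slices: np.ndarray | None = None  # (freqs, electrodes) bool, zero-SD at z-scoring

    @property
    def per_trial(self) -> bool:
        return self.data.ndim == 4


@dataclass
class ICCResult:
    """Across-session agreement per electrode."""

    icc: np.ndarray                  # (n_electrodes,)
    n_sessions: int
    form: str = "ICC(2,1)"
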