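"""Ground-truthed synthetic data: wideband spike recordings, event-locked LFP
sessions and multi-session series.

The generators emulate the statistical structure the downstream analyses
assume — spike waveforms that appear with attenuation on neighbouring wires
of a 16-channel bundle, Poisson spiking with an absolute refractory period,
1/f LFP background with a shared common-mode component, event-locked
oscillatory bursts, occasional high-amplitude artifact trials, and
session-to-session variability with an analytically known intraclass
correlation.  Every dataset ships with a :class:`~ephysforge.types.GroundTruth`
describing exactly what was planted.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .types import (
    EXCITATORY,
    INHIBITORY,
    ChannelMeta,
    ContinuousRecording,
    EventTable,
    GroundTruth,
    OscillationSpec,
    SimulationSpec,
    SpikeTemplate,
    TFTensor,
)

log = logging.getLogger(__name__)

# Peak-to-trough width and afterhyperpolarization (AHP) duration ranges, ms.
# The two cell classes occupy disjoint ranges so that the feature dichotomy
# (fast-spiking narrow/brief vs regular-spiking broad/long) is separable by
# construction.
INHIBITORY_WIDTH_MS = (0.15, 0.30)
EXCITATORY_WIDTH_MS = (0.45, 0.70)
INHIBITORY_AHP_MS = (0.15, 0.35)
EXCITATORY_AHP_MS = (0.50, 0.80)

# time above 20% of the peak for a Gaussian tail: t = sigma * sqrt(2 ln 5)
_AHP_SIGMA_FACTOR = float(np.sqrt(2.0 * np.log(5.0)))


def _biphasic_waveform(
    snippet_len: int,
    sampling_rate_hz: float,
    width_ms: float,
    ahp_ms: float,
    trough_uv: float,
    peak_frac: float = 0.35,
) -> tuple[np.ndarray, float]:
    """Trough-then-peak action-potential shape with controlled geometry.

    The trough is a narrow Gaussian; the repolarization peak is an asymmetric
    Gaussian whose falling flank is sized so that the tail stays above 20% of
    the peak for exactly ``ahp_ms`` after the peak.  Returns the waveform and
    the grid-snapped width actually realized.
    """
    fs = sampling_rate_hz
    t_trough = int(round(0.8e-3 * fs))           # matches the sorter's pre-window
    width_samples = max(2, int(round(width_ms * 1e-3 * fs)))
    t_peak = t_trough + width_samples
    if t_peak >= snippet_len - 2:
        raise ValueError("snippet_len too short for the requested width")

    t = np.arange(snippet_len, dtype=float)
    # flanks narrow relative to the trough-peak gap, so the planted extrema
    # positions survive superposition exactly
    sigma_trough = min(0.10e-3 * fs, width_samples / 4.0)
    trough = -abs(trough_uv) * np.exp(-((t - t_trough) ** 2) / (2 * sigma_trough**2))

    peak_uv = peak_frac * abs(trough_uv)
    sigma_rise = width_samples / 4.0
    sigma_fall = (ahp_ms * 1e-3 * fs) / _AHP_SIGMA_FACTOR
    peak = np.where(
        t <= t_peak,
        peak_uv * np.exp(-((t - t_peak) ** 2) / (2 * sigma_rise**2)),
        peak_uv * np.exp(-((t - t_peak) ** 2) / (2 * sigma_fall**2)),
    )
    return trough + peak, width_samples / fs * 1e3


def generate_spike_templates(
    n_excitatory: int,
    n_inhibitory: int,
    snippet_len: int = 64,
    seed: int = 0,
    *,
    sampling_rate_hz: float = 25_000.0,
    bundle_size: int = 16,
    peak_to_peak_uv: float | Sequence[float] = 110.0,
    gain_decay_range: tuple[float, float] = (0.12, 0.30),
    n_bundles: int = 1,
) -> list[SpikeTemplate]:
    """Draw spike templates for two waveform classes with disjoint feature ranges.

    Channel gains within a bundle decay geometrically with nominal wire
    distance, so each unit is visible above 20% gain on 1–4 neighbouring
    sites.  Templates are spread round-robin over ``n_bundles`` bundles.
    Deterministic given ``seed``.
    """
    if n_excitatory < 0 or n_inhibitory < 0:
        raise ValueError("template counts must be >= 0")
    if snippet_len < 32:
        raise ValueError("snippet_len must be >= 32 samples")
    rng = np.random.default_rng(seed)
    n_total = n_excitatory + n_inhibitory
    p2p = np.broadcast_to(np.asarray(peak_to_peak_uv, dtype=float), (n_total,))

    labels = [EXCITATORY] * n_excitatory + [INHIBITORY] * n_inhibitory
    # Distinct primary wires per bundle: each wire sees its nearest neuron,
    # so two units never share an identical footprint within one bundle.
    primary_pool: dict[int, list[int]] = {}
    templates: list[SpikeTemplate] = []
    for uid, label in enumerate(labels):
        if label == EXCITATORY:
            width = rng.uniform(*EXCITATORY_WIDTH_MS)
            ahp = rng.uniform(*EXCITATORY_AHP_MS)
        else:
            width = rng.uniform(*INHIBITORY_WIDTH_MS)
            ahp = rng.uniform(*INHIBITORY_AHP_MS)
        wf, realized_width = _biphasic_waveform(
            snippet_len, sampling_rate_hz, width, ahp, trough_uv=1.0
        )
        wf = wf * (p2p[uid] / np.ptp(wf))

        bundle = uid % n_bundles
        if not primary_pool.get(bundle):
            primary_pool[bundle] = list(rng.permutation(bundle_size))
        primary = int(primary_pool[bundle].pop())
        decay = rng.uniform(*gain_decay_range)
        gains = decay ** np.abs(np.arange(bundle_size) - primary)
        templates.append(
            SpikeTemplate(
                unit_id=uid,
                waveform=wf,
                class_label=label,
                channel_gains=gains,
                bundle=bundle,
                width_ms=realized_width,
                hyperpolarization_ms=ahp,
            )
        )
    return templates


# class centroids in (peak-to-trough width, AHP duration) ms for planted
# waveform-feature populations; compact clouds, well inside the template ranges
_EI_CENTROIDS = {
    EXCITATORY: (0.575, 0.675),
    INHIBITORY: (0.225, 0.250),
    "outlier": (0.390, 0.440),
}


def generate_ei_features(
    n_excitatory: int,
    n_inhibitory: int,
    n_outlier: int = 0,
    seed: int = 0,
    spread_ms: float = 0.035,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted (width, AHP) feature populations for the three waveform classes.

    Clouds are Gaussian around class centroids with SD ``spread_ms``, small
    against the between-class separation, emulating well-separated putative
    cell types.  Returns (features (n, 2), true labels).
    """
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for name, n in ((EXCITATORY, n_excitatory), (INHIBITORY, n_inhibitory),
                    ("outlier", n_outlier)):
        cx, cy = _EI_CENTROIDS[name]
        feats.append(np.column_stack([rng.normal(cx, spread_ms, n), rng.normal(cy, spread_ms, n)]))
        labels += [name] * n
    return np.vstack(feats), np.asarray(labels)


def generate_spike_trains(spec: SimulationSpec) -> dict[int, np.ndarray]:
    """Homogeneous Poisson trains with an absolute dead-time.

    Spikes closer than ``spec.refractory_ms`` to the previous kept spike are
    censored, so no returned train violates the refractory period.
    """
    if spec.duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(spec.seed)
    refractory_s = spec.refractory_ms * 1e-3
    trains: dict[int, np.ndarray] = {}
    for uid, rate in enumerate(spec.unit_rates_hz):
        n = rng.poisson(rate * spec.duration_s)
        times = np.sort(rng.uniform(0.0, spec.duration_s, size=n))
        kept: list[float] = []
        last = -np.inf
        for t in times:
            if t - last >= refractory_s:
                kept.append(t)
                last = t
        trains[uid] = np.asarray(kept)
    return trains


def render_extracellular(
    templates: Sequence[SpikeTemplate],
    trains: dict[int, np.ndarray],
    spec: SimulationSpec,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Superpose spike templates on Gaussian background noise.

    The trace is the linear sum over units and spikes of template × channel
    gain, inserted so the template trough lands on the spike sample, plus
    white noise of SD ``noise_sd_uv`` and an optional common-mode component
    shared by every channel.  Wideband: no filtering is applied here.
    """
    fs = spec.sampling_rate_hz
    n_samples = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    trace = rng.normal(0.0, spec.noise_sd_uv, size=(n_samples, spec.n_channels)) \
        if spec.noise_sd_uv > 0 else np.zeros((n_samples, spec.n_channels))

    common = None
    if spec.common_mode_amplitude_uv > 0:
        common = rng.normal(0.0, spec.common_mode_amplitude_uv, size=n_samples)
        trace += common[:, None]

    bundle_map = spec.bundle_map
    dropped = 0
    kept_trains: dict[int, np.ndarray] = {}
    for tpl in templates:
        times = trains.get(tpl.unit_id)
        if times is None:
            continue
        chans = np.flatnonzero(bundle_map == tpl.bundle)
        if chans.size == 0:
            raise ValueError(f"template bundle {tpl.bundle} absent from bundle map")
        trough = int(np.argmin(tpl.waveform))
        L = len(tpl.waveform)
        footprint = np.outer(tpl.waveform, tpl.channel_gains[: chans.size])
        kept = []
        for t in times:
            s = int(round(t * fs))
            start = s - trough
            if start < 0 or start + L > n_samples:
                dropped += 1
                continue
            trace[start : start + L, chans] += footprint
            kept.append(t)
        kept_trains[tpl.unit_id] = np.asarray(kept)
    if dropped:
        log.info("render_extracellular: %d spikes fell outside the trace and were skipped", dropped)

    meta = [ChannelMeta(index=i, bundle=int(bundle_map[i])) for i in range(spec.n_channels)]
    rec = ContinuousRecording(data=trace, sampling_rate_hz=fs, channel_meta=meta)
    gt = GroundTruth(
        spike_times_per_unit=kept_trains,
        templates=list(templates),
        dropped_spikes=dropped,
    )
    if common is not None:
        gt.session_effects.append({"common_mode_trace_sd": float(np.std(common))})
    return rec, gt


def simulate_spike_session(
    spec: SimulationSpec,
    n_excitatory: int = 4,
    n_inhibitory: int = 1,
    *,
    snippet_len: int = 64,
    peak_to_peak_uv: float = 110.0,
    units_per_bundle: int | None = None,
) -> tuple[ContinuousRecording, GroundTruth]:
    """Convenience: templates + trains + rendering in one deterministic call.

    Templates are distributed over every 16-channel bundle of the probe.
    """
    n_bundles = spec.n_channels // spec.bundle_size
    if units_per_bundle is not None:
        total = units_per_bundle * n_bundles
        n_inhibitory = max(1, int(round(total * n_inhibitory / max(1, n_excitatory + n_inhibitory))))
        n_excitatory = total - n_inhibitory
    templates = generate_spike_templates(
        n_excitatory,
        n_inhibitory,
        snippet_len,
        seed=spec.seed,
        sampling_rate_hz=spec.sampling_rate_hz,
        bundle_size=spec.bundle_size,
        peak_to_peak_uv=peak_to_peak_uv,
        n_bundles=n_bundles,
    )
    n_units = len(templates)
    if len(spec.unit_rates_hz) != n_units:
        rng = np.random.default_rng(spec.seed + 1)
        rates = rng.uniform(2.0, 8.0, size=n_units)
        spec = SimulationSpec(**{**spec.__dict__, "unit_rates_hz": tuple(rates)})
    trains = generate_spike_trains(spec)
    return render_extracellular(templates, trains, spec)


def _one_over_f_noise(rng: np.random.Generator, n_samples: int, sd: float) -> np.ndarray:
    """Noise with power spectral density ∝ 1/f, scaled to the requested SD."""
    white = rng.normal(size=n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]
    shaped = np.fft.irfft(spec / np.sqrt(f), n=n_samples)
    return shaped * (sd / np.std(shaped))


def generate_lfp_session(
    spec: SimulationSpec,
    oscillations: Sequence[OscillationSpec],
    n_trials: int,
    *,
    epoch_window_s: tuple[float, float] = (-1.0, 2.0),
    iti_s: float = 4.0,
    artifact_amplitude_factor: float = 15.0,
) -> tuple[ContinuousRecording, EventTable, GroundTruth]:
    """One event-locked LFP session: 1/f background + common mode + bursts.

    Each electrode carries independent 1/f noise plus a component shared by
    all electrodes; event-locked sinusoidal bursts (Hann-windowed) are added
    per ``oscillations``.  A random ``artifact_trial_fraction`` of trials
    receives a broadband high-amplitude transient spanning the epoch window.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    fs = spec.sampling_rate_hz
    nyq = fs / 2.0
    for osc in oscillations:
        if osc.center_hz >= nyq:
            raise ValueError(f"oscillation at {osc.center_hz} Hz is at/above Nyquist ({nyq} Hz)")

    rng = np.random.default_rng(spec.seed)
    pre, post = epoch_window_s
    event_times = (1.0 - pre) + iti_s * np.arange(n_trials) + rng.uniform(0, 0.5, n_trials)
    duration = event_times[-1] + post + 1.0
    n_samples = int(round(duration * fs))

    n_e = spec.n_channels
    trace = np.empty((n_samples, n_e))
    for e in range(n_e):
        trace[:, e] = _one_over_f_noise(rng, n_samples, spec.noise_sd_uv)
    if spec.common_mode_amplitude_uv > 0:
        trace += _one_over_f_noise(rng, n_samples, spec.common_mode_amplitude_uv)[:, None]

    types = list(spec.event_mix)
    probs = np.array([spec.event_mix[t] for t in types])
    trial_types = rng.choice(types, size=n_trials, p=probs)
    response_times = event_times + rng.uniform(0.3, 1.5, n_trials)

    t_axis = np.arange(n_samples) / fs
    for osc in oscillations:
        for i, ev in enumerate(event_times):
            if osc.trial_types is not None and trial_types[i] not in osc.trial_types:
                continue
            a = int(round((ev + osc.onset_s) * fs))
            b = int(round((ev + osc.offset_s) * fs))
            a, b = max(a, 0), min(b, n_samples)
            if b <= a:
                continue
            phase = rng.uniform(0, 2 * np.pi)
            burst = osc.amplitude_uv * np.sin(
                2 * np.pi * osc.center_hz * t_axis[a:b] + phase
            ) * hann(b - a)
            for e in osc.electrodes:
                trace[a:b, e] += burst

    artifact_trials = np.flatnonzero(rng.random(n_trials) < spec.artifact_trial_fraction)
    win_len = int(round((post - pre) * fs))
    env = hann(win_len)
    background_sd = float(trace.std())   # realized 1/f + common-mode background
    for i in artifact_trials:
        a = int(round((event_times[i] + pre) * fs))
        burst = artifact_amplitude_factor * background_sd * rng.normal(size=win_len) * env
        trace[a : a + win_len, :] += burst[:, None]

    meta = [ChannelMeta(index=e, bundle=0, region="lfp") for e in range(n_e)]
    rec = ContinuousRecording(data=trace, sampling_rate_hz=fs, channel_meta=meta)
    events = EventTable(
        frame=pd.DataFrame(
            {"time_s": event_times, "trial_type": trial_types, "response_time_s": response_times}
        )
    )
    gt = GroundTruth(artifact_trials=artifact_trials, oscillations=list(oscillations))
    return rec, events, gt


def generate_session_series(
    n_sessions: int,
    *,
    signal_sd: float = 1.0,
    noise_sd: float = 1.0,
    n_times: int = 100,
    n_freqs: int = 100,
    n_electrodes: int = 32,
    seed: int = 0,
) -> tuple[list[TFTensor], GroundTruth]:
    """Multi-session time-frequency stacks with known across-session agreement.

    Every session shares one deterministic signal tensor (SD ``signal_sd``)
    and receives independent Gaussian noise (SD ``noise_sd``), so the expected
    intraclass correlation is the variance ratio
    ``signal_sd² / (signal_sd² + noise_sd²)``.
    """
    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2 (ICC undefined for a single session)")
    rng = np.random.default_rng(seed)
    shape = (n_times, n_freqs, n_electrodes)
    signal = rng.normal(0.0, signal_sd, shape) if signal_sd > 0 else np.zeros(shape)
    times = np.arange(n_times) * 0.01
    freqs = np.linspace(2.0, 70.0, n_freqs)
    sessions = []
    effects = []
    for s in range(n_sessions):
        noise = rng.normal(0.0, noise_sd, shape) if noise_sd > 0 else 0.0
        sessions.append(TFTensor(data=signal + noise, times_s=times, freqs_hz=freqs))
        effects.append({"session": s, "noise_sd": noise_sd})
    gt = GroundTruth(session_effects=effects)
    expected = signal_sd**2 / (signal_sd**2 + noise_sd**2) if (signal_sd or noise_sd) else 1.0
    gt.session_effects.append({"expected_icc": expected})
    return sessions, gt
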