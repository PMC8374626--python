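"""Event-locked LFP analysis chain.

Order is fixed and enforced by state flags: epoch → artifact-trial rejection
(on raw epochs) → across-electrode median referencing → Morlet time-frequency
decomposition → baseline subtraction → trial-type averaging → z-scoring →
across-session intraclass correlation (ICC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import (
    STATE_BASELINED,
    STATE_RAW,
    STATE_ZSCORED,
    ContinuousRecording,
    EpochedLFP,
    EventTable,
    ICCResult,
    TFTensor,
)

log = logging.getLogger(__name__)


@dataclass
class TFParams:
    """Morlet decomposition and artifact-rejection settings.

    The two-element cycles parameter [cycles_base, cycles_factor] follows the
    expanding-wavelet convention: the number of cycles at frequency f is
    ``c(f) = cycles_base · (f / freq_min)^(1 − cycles_factor)`` — constant
    cycles at factor 1, fixed (FFT-like) window at factor 0.
    """

    freq_min_hz: float = 2.0
    freq_max_hz: float = 70.0
    cycles_base: float = 2.0
    cycles_factor: float = 0.7
    n_freqs: int = 40
    log_spaced: bool = True
    baseline_window_s: tuple[float, float] = (-0.5, 0.0)
    artifact_k: float = 4.0
    display_band_hz: tuple[float, float] = (8.0, 20.0)
    out_step_s: float = 0.01          # time resolution of the TF output
    wavelet_support_sd: float = 3.5   # envelope truncation, in Gaussian SDs

    def __post_init__(self) -> None:
        if self.cycles_base <= 0:
            raise ValueError("cycles_base must be > 0")
        if not 0 <= self.cycles_factor <= 1:
            raise ValueError("cycles_factor must be in [0, 1]")
        if self.artifact_k <= 0:
            raise ValueError("artifact_k must be > 0")

    def frequencies(self) -> np.ndarray:
        if self.log_spaced:
            return np.geomspace(self.freq_min_hz, self.freq_max_hz, self.n_freqs)
        return np.linspace(self.freq_min_hz, self.freq_max_hz, self.n_freqs)

    def cycles_at(self, f: np.ndarray | float) -> np.ndarray | float:
        return self.cycles_base * (np.asarray(f) / self.freq_min_hz) ** (1.0 - self.cycles_factor)


def epoch(
    recording: ContinuousRecording,
    events: EventTable,
    window_s: tuple[float, float] = (-1.0, 2.0),
    lock: str = "time_s",
) -> EpochedLFP:
    """Cut a trial × time × electrode tensor around behavioral events.

    ``lock`` selects the event-table column used as t=0 (trial onset
    ``time_s`` or ``response_time_s``).  Events whose window falls outside
    the recording are dropped and logged.
    """
    fs = recording.sampling_rate_hz
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("window must have positive length")
    lock_times = events.frame[lock].to_numpy(dtype=float)
    a = int(round(lo * fs))
    b = int(round(hi * fs))
    n_t = b - a
    trials, labels, dropped = [], [], 0
    for t0, lab in zip(lock_times, events.trial_types):
        s = int(round(t0 * fs))
        if s + a < 0 or s + b > recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.data[s + a : s + b, :])
        labels.append(lab)
    if dropped:
        log.info("epoch: dropped %d out-of-range events", dropped)
    if not trials:
        raise ValueError("no usable events within the recording")
    return EpochedLFP(
        data=np.stack(trials),
        times_s=(np.arange(n_t) + a) / fs,
        trial_labels=np.asarray(labels),
        sampling_rate_hz=fs,
    )


def reject_artifact_trials(epochs: EpochedLFP, artifact_k: float = 4.0) -> np.ndarray:
    """Flag noisy trials by the trial-SD rule.

    Per trial, the SD over time is computed for each electrode and averaged
    across electrodes; a trial whose average SD exceeds ``artifact_k`` times
    the mean over all trials is flagged.  Runs on raw (pre-referencing)
    epochs; the data are untouched, only the boolean mask is returned
    (True = rejected).
    """
    if epochs.referenced:
        raise ValueError("artifact rejection must run before median referencing")
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    s = epochs.data.std(axis=1).mean(axis=1)          # (n_trials,)
    rejected = s > artifact_k * s.mean()
    if rejected.all():
        raise ValueError("all trials rejected as artifacts")
    return rejected


def median_reference(epochs: EpochedLFP) -> EpochedLFP:
    """Subtract the across-electrode median at every trial × time point."""
    if epochs.referenced:
        raise ValueError("epochs already median-referenced")
    if epochs.n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    med = np.median(epochs.data, axis=2, keepdims=True)
    return EpochedLFP(
        data=epochs.data - med,
        times_s=epochs.times_s,
        trial_labels=epochs.trial_labels,
        sampling_rate_hz=epochs.sampling_rate_hz,
        rejected=epochs.rejected,
        referenced=True,
    )


def _morlet_wavelet(f: float, cycles: float, fs: float, support_sd: float) -> np.ndarray:
    sigma_t = cycles / (2 * np.pi * f)
    half = int(np.ceil(support_sd * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2 * sigma_t**2))
    w = env * np.exp(2j * np.pi * f * t)
    # unit gain for a unit-amplitude sinusoid at f
    return w * (2.0 / env.sum())


def morlet_tf(epochs: EpochedLFP, params: TFParams | None = None) -> TFTensor:
    """Per-trial Morlet amplitude tensor (trials × times × freqs × electrodes).

    Each frequency is convolved with a complex Morlet wavelet of
    ``params.cycles_at(f)`` cycles; amplitude is the modulus of the analytic
    signal.  Edge samples whose wavelet support exceeds the epoch are NaN,
    so later baselines never include edge artifacts.  The output time axis
    is decimated to ``params.out_step_s``.
    """
    params = params or TFParams()
    if not epochs.referenced:
        raise ValueError("median-reference the epochs before TF decomposition")
    fs = epochs.sampling_rate_hz
    if params.freq_max_hz >= fs / 2:
        raise ValueError(f"freq_max {params.freq_max_hz} Hz at/above Nyquist ({fs/2} Hz)")
    freqs = params.frequencies()
    n_trials, n_t, n_e = epochs.data.shape

    f0 = freqs.min()
    min_window = 2 * params.wavelet_support_sd * params.cycles_at(f0) / (2 * np.pi * f0)
    if n_t / fs < min_window:
        raise ValueError(
            f"epoch window {n_t / fs:.2f} s shorter than the {f0:.1f} Hz wavelet "
            f"support; need at least {min_window:.2f} s"
        )

    step = max(1, int(round(params.out_step_s * fs)))
    t_idx = np.arange(0, n_t, step)
    flat = epochs.data.transpose(0, 2, 1).reshape(n_trials * n_e, n_t)
    out = np.empty((n_trials, len(t_idx), len(freqs), n_e))
    for fi, f in enumerate(freqs):
        w = _morlet_wavelet(f, float(params.cycles_at(f)), fs, params.wavelet_support_sd)
        conv = signal.fftconvolve(flat, w[None, :], mode="same", axes=1)
        amp = np.abs(conv)
        half = len(w) // 2
        amp[:, :half] = np.nan
        amp[:, n_t - half :] = np.nan
        out[:, :, fi, :] = amp[:, t_idx].reshape(n_trials, n_e, len(t_idx)).transpose(0, 2, 1)
    return TFTensor(
        data=out,
        times_s=epochs.times_s[t_idx],
        freqs_hz=freqs,
        state=STATE_RAW,
        trial_labels=epochs.trial_labels,
    )


def baseline_subtract(tf: TFTensor, baseline_window_s: tuple[float, float] = (-0.5, 0.0)) -> TFTensor:
    """Subtract the pre-event mean per (electrode, frequency) to expose evoked change."""
    if tf.state != STATE_RAW:
        raise ValueError(f"baseline subtraction requires a raw tensor, got {tf.state!r}")
    lo, hi = baseline_window_s
    in_base = (tf.times_s >= lo) & (tf.times_s < hi)
    if not in_base.any():
        raise ValueError("baseline window does not intersect the epoch")
    if tf.per_trial:
        base = np.nanmean(tf.data[:, in_base, :, :], axis=(0, 1))   # (freqs, electrodes)
        data = tf.data - base[None, None, :, :]
    else:
        base = np.nanmean(tf.data[in_base, :, :], axis=0)
        data = tf.data - base[None, :, :]
    if np.isnan(base).any():
        raise ValueError("baseline window contains no valid (non-edge) samples")
    return TFTensor(
        data=data,
        times_s=tf.times_s,
        freqs_hz=tf.freqs_hz,
        state=STATE_BASELINED,
        trial_labels=tf.trial_labels,
    )


def average_by_trial_type(
    tf: TFTensor,
    rejected: np.ndarray | None = None,
    trial_types: list[str] | None = None,
) -> dict[str, TFTensor]:
    """Mean TF tensor over surviving trials of each trial type."""
    if not tf.per_trial:
        raise ValueError("need a per-trial tensor to average by trial type")
    if tf.trial_labels is None:
        raise ValueError("tensor carries no trial labels")
    keep = np.ones(tf.data.shape[0], dtype=bool) if rejected is None else ~np.asarray(rejected)
    wanted = trial_types or list(dict.fromkeys(tf.trial_labels.tolist()))
    out: dict[str, TFTensor] = {}
    for tt in wanted:
        sel = keep & (tf.trial_labels == tt)
        if not sel.any():
            log.warning("trial type %r has no surviving trials; omitted", tt)
            continue
        out[tt] = TFTensor(
            data=tf.data[sel].mean(axis=0),
            times_s=tf.times_s,
            freqs_hz=tf.freqs_hz,
            state=tf.state,
        )
    return out


def zscore_tf(tf: TFTensor) -> TFTensor:
    """Z-score each (electrode, frequency) slice across time.

    Zero-SD slices are set to 0 and flagged.  Idempotent to float tolerance.
    """
    data = tf.data
    axes = (0, 1) if tf.per_trial else (0,)
    mean = np.nanmean(data, axis=axes, keepdims=True)
    sd = np.nanstd(data, axis=axes, keepdims=True)
    degenerate = np.squeeze(sd == 0, axis=axes)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (data - mean) / safe_sd
    z = np.where(np.broadcast_to(sd == 0, z.shape), 0.0, z)
    return TFTensor(
        data=z,
        times_s=tf.times_s,
        freqs_hz=tf.freqs_hz,
        state=STATE_ZSCORED,
        trial_labels=tf.trial_labels,
        degenerate_slices=degenerate,
    )


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is (n_subjects, k_raters).  Closed-form from the two-way
    ANOVA mean squares.
    """
    Y = np.asarray(ratings, dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return 1.0 if msr > 0 else 0.0
    return float((msr - mse) / denom)


def session_icc(sessions: list[TFTensor] | list[np.ndarray], form: str = "ICC(2,1)") -> ICCResult:
    """Across-session agreement per electrode.

    Each time × frequency bin is a subject and each session a rater; the
    default form is two-way random effects, absolute agreement, single
    rater — ICC(2,1).  Only bins finite in every session enter.
    """
    if form != "ICC(2,1)":
        raise ValueError(f"unsupported ICC form {form!r}")
    arrays = [s.data if isinstance(s, TFTensor) else np.asarray(s, float) for s in sessions]
    if len(arrays) < 2:
        raise ValueError("need >= 2 sessions")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("session tensors must share one shape (times, freqs, electrodes)")
    n_e = shape[-1]
    stack = np.stack([a.reshape(-1, n_e) for a in arrays], axis=-1)   # (bins, e, sessions)
    icc = np.empty(n_e)
    for e in range(n_e):
        ratings = stack[:, e, :]
        valid = np.all(np.isfinite(ratings), axis=1)
        icc[e] = icc_2_1(ratings[valid])
    return ICCResult(icc=icc, n_sessions=len(arrays), form=form)


def band_filter_trace(
    epochs: EpochedLFP, band_hz: tuple[float, float] = (8.0, 20.0), order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass of the epoched traces (for display/export)."""
    lo, hi = band_hz
    nyq = epochs.sampling_rate_hz / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band_hz} invalid for Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, epochs.data, axis=1)


def session_tf_pipeline(
    recording: ContinuousRecording,
    events: EventTable,
    params: TFParams | None = None,
    window_s: tuple[float, float] = (-1.0, 2.0),
) -> tuple[dict[str, TFTensor], np.ndarray]:
    """Full single-session chain, returning z-scored per-type averages and
    the artifact mask."""
    params = params or TFParams()
    ep = epoch(recording, events, window_s)
    rejected = reject_artifact_trials(ep, params.artifact_k)
    ep = median_reference(ep)
    tf = morlet_tf(ep, params)
    tf = baseline_subtract(tf, params.baseline_window_s)
    by_type = average_by_trial_type(tf, rejected=rejected)
    return {tt: zscore_tf(t) for tt, t in by_type.items()}, rejected
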