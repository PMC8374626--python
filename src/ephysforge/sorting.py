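"""Polytrode spike sorting: band-pass filtering, group-median referencing,
amplitude-threshold detection, wavelet feature selection and clustering.

Channels are processed as fixed 16-wire "polytrode" groups (two cannula
bundles).  Detection thresholds at a multiple of a per-channel robust noise
SD; snippets are cut across the whole group and concatenated channel-wise
before featurization, so a unit visible on several neighbouring wires is
sorted once rather than counted per wire.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal, stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .types import (
    ContinuousRecording,
    SpikeEvent,
    SpikeEventSet,
    UnitCluster,
)

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Filtering, channel-exclusion and detection settings.

    threshold_k multiplies the per-channel noise SD; the robust estimator
    median(|v|)/0.6745 is the default so that spikes themselves do not
    inflate the threshold.
    """

    band_low_hz: float = 300.0
    band_high_hz: float = 3000.0
    threshold_k: float = 5.0
    snippet_pre_ms: float = 0.8
    snippet_post_ms: float = 1.7
    broken_impedance_mohm: float = 10.0
    polytrode_size: int = 16
    robust_noise_sd: bool = True      # False = plain standard deviation
    bipolar: bool = True              # detect on |v| rather than -v
    cross_channel_merge_ms: float = 0.5
    filter_order: int = 4

    def snippet_samples(self, fs: float) -> tuple[int, int]:
        return int(round(self.snippet_pre_ms * 1e-3 * fs)), int(
            round(self.snippet_post_ms * 1e-3 * fs)
        )


@dataclass
class ClusterParams:
    n_features: int = 24   # concatenated 16-channel snippets need more than a single wire's 10
    k_max: int = 10
    merge_correlation: float = 0.95
    merge_isi_limit: float = 0.015
    isi_violation_ms: float = 3.0
    wavelet: str = "haar"
    seed: int = 0


def bandpass(recording: ContinuousRecording, params: DetectionParams) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass (forward-backward), DC removed."""
    nyq = recording.sampling_rate_hz / 2.0
    if not 0 < params.band_low_hz < params.band_high_hz:
        raise ValueError("need 0 < band_low < band_high")
    if params.band_high_hz >= nyq:
        raise ValueError(f"band edge {params.band_high_hz} Hz at/above Nyquist ({nyq} Hz)")
    sos = signal.butter(
        params.filter_order,
        [params.band_low_hz, params.band_high_hz],
        btype="bandpass",
        fs=recording.sampling_rate_hz,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, recording.data, axis=0)
    return ContinuousRecording(
        data=filtered,
        sampling_rate_hz=recording.sampling_rate_hz,
        channel_meta=recording.channel_meta,
    )


def exclude_broken_channels(
    recording: ContinuousRecording, params: DetectionParams
) -> np.ndarray:
    """Usable-channel mask: broken wires and impedances above 10 MOhm are dropped.

    Channels without impedance metadata are treated as usable (logged).
    """
    mask = np.ones(recording.n_channels, dtype=bool)
    n_missing = 0
    for i, m in enumerate(recording.channel_meta):
        if m.broken:
            mask[i] = False
        elif m.impedance_mohm is None:
            n_missing += 1
        elif m.impedance_mohm > params.broken_impedance_mohm:
            mask[i] = False
    if n_missing:
        log.info("%d channels lack impedance metadata; treated as usable", n_missing)
    if not mask.any():
        raise ValueError("all channels excluded: nothing to sort")
    return mask


def median_reference_polytrode(
    recording: ContinuousRecording,
    mask: np.ndarray | None = None,
) -> ContinuousRecording:
    """Subtract, per sample, the median across usable channels of each 16-wire group.

    Groups with fewer than 2 usable channels pass through unreferenced.
    """
    if mask is None:
        mask = np.ones(recording.n_channels, dtype=bool)
    out = recording.data.copy()
    bundles = recording.bundle_map
    for b in np.unique(bundles):
        chans = np.flatnonzero(bundles == b)
        usable = chans[mask[chans]]
        if usable.size < 2:
            log.warning("polytrode group %d has <2 usable channels; left unreferenced", b)
            continue
        med = np.median(recording.data[:, usable], axis=1)
        out[:, chans] -= med[:, None]
    return ContinuousRecording(
        data=out,
        sampling_rate_hz=recording.sampling_rate_hz,
        channel_meta=recording.channel_meta,
    )


def estimate_noise_sd(trace: np.ndarray, robust: bool = True) -> float:
    """Per-channel noise SD; the robust form is median(|v|)/0.6745."""
    if robust:
        return float(np.median(np.abs(trace)) / 0.6745)
    return float(np.std(trace))


def detect_spikes(
    referenced: ContinuousRecording,
    params: DetectionParams,
    mask: np.ndarray | None = None,
) -> list[SpikeEventSet]:
    """Threshold detection at ``threshold_k`` × noise SD per channel, one
    :class:`SpikeEventSet` per polytrode group.

    Crossings within the snippet length on one channel merge to the largest
    excursion; crossings within ±0.5 ms across channels of a group collapse
    to one event at the largest-amplitude channel.  Snippets are cut around
    the aligned extremum on every usable channel of the group.
    """
    fs = referenced.sampling_rate_hz
    if mask is None:
        mask = np.ones(referenced.n_channels, dtype=bool)
    pre, post = params.snippet_samples(fs)
    snip_len = pre + post
    merge_gap = int(round(params.cross_channel_merge_ms * 1e-3 * fs))
    bundles = referenced.bundle_map

    out: list[SpikeEventSet] = []
    for b in np.unique(bundles):
        chans = np.flatnonzero(bundles == b)
        usable = chans[mask[chans]]
        candidates: list[tuple[int, int, float]] = []   # (sample, channel, |amp|)
        for ch in usable:
            v = referenced.data[:, ch]
            sd = estimate_noise_sd(v, params.robust_noise_sd)
            if sd == 0:
                log.info("channel %d flat (sd=0); skipped", ch)
                continue
            thr = params.threshold_k * sd
            if not np.isfinite(thr):
                continue
            x = np.abs(v) if params.bipolar else -v
            peaks, props = signal.find_peaks(x, height=thr, distance=snip_len)
            for p, h in zip(peaks, props["peak_heights"]):
                candidates.append((int(p), int(ch), float(h)))
        if not candidates:
            out.append(
                SpikeEventSet(
                    group=int(b),
                    events=[],
                    snippets=np.empty((0, snip_len, usable.size)),
                    group_channels=usable,
                    sampling_rate_hz=fs,
                )
            )
            continue

        candidates.sort()
        merged: list[SpikeEvent] = []
        cur = candidates[0]
        for nxt in candidates[1:]:
            if nxt[0] - cur[0] <= merge_gap:
                if nxt[2] > cur[2]:
                    cur = nxt
            else:
                merged.append(SpikeEvent(sample=cur[0], channel=cur[1], amplitude_uv=cur[2]))
                cur = nxt
        merged.append(SpikeEvent(sample=cur[0], channel=cur[1], amplitude_uv=cur[2]))

        events, snippets = [], []
        for ev in merged:
            # align to the absolute-maximum sample of the best channel near the crossing
            a = max(ev.sample - merge_gap, 0)
            z = min(ev.sample + merge_gap + 1, referenced.n_samples)
            seg = referenced.data[a:z, ev.channel]
            peak = a + int(np.argmax(np.abs(seg)))
            if peak - pre < 0 or peak + post > referenced.n_samples:
                continue
            events.append(SpikeEvent(sample=peak, channel=ev.channel, amplitude_uv=ev.amplitude_uv))
            snippets.append(referenced.data[peak - pre : peak + post, usable])
        out.append(
            SpikeEventSet(
                group=int(b),
                events=events,
                snippets=np.asarray(snippets) if snippets else np.empty((0, snip_len, usable.size)),
                group_channels=usable,
                sampling_rate_hz=fs,
            )
        )
    return out


def wavelet_features(
    snippets: np.ndarray,
    n_features: int = 24,
    wavelet: str = "haar",
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-wavelet coefficients of concatenated snippets, ranked by
    deviation from normality across spikes.

    The score is the one-sample Kolmogorov–Smirnov statistic of each
    coefficient against a Gaussian fitted to it; multimodal (cluster-
    separating) coefficients score high.  Ties break by variance, then index.
    Fewer than 10 snippets fall back to principal components.

    Returns (feature matrix, selected coefficient indices; indices are
    negative for the PCA fallback).
    """
    X = np.asarray(snippets, dtype=float)
    if X.ndim == 3:
        n, t, c = X.shape
        X = X.transpose(0, 2, 1).reshape(n, t * c)
    n, d = X.shape
    if n < 10:
        log.info("only %d snippets; falling back to principal components", n)
        k = min(n_features, max(1, min(n, d) - 1))
        pcs = PCA(n_components=k, random_state=0).fit_transform(X)
        return pcs, -np.arange(1, k + 1)

    snips = np.asarray(snippets, dtype=float)
    if snips.ndim == 2:
        snips = snips[:, :, None]
    _, snip_len, n_ch = snips.shape
    max_level = pywt.dwt_max_level(snip_len, wavelet)
    level = min(4, max_level)
    if level < 1:
        log.info("snippet length %d too short for %s decomposition; using raw samples", snip_len, wavelet)
        coeffs = X
        channel_of = np.repeat(np.arange(n_ch), snip_len)
    else:
        if level < 4:
            log.info("wavelet depth reduced to %d for snippet length %d", level, snip_len)
        blocks, owners = [], []
        for ch in range(n_ch):
            dec = np.hstack(pywt.wavedec(snips[:, :, ch], wavelet, level=level, axis=1))
            blocks.append(dec)
            owners.append(np.full(dec.shape[1], ch))
        coeffs = np.hstack(blocks)
        channel_of = np.concatenate(owners)

    n_coef = coeffs.shape[1]
    ks = np.zeros(n_coef)
    var = coeffs.var(axis=0)
    for j in range(n_coef):
        col = coeffs[:, j]
        sd = col.std()
        if sd == 0:
            ks[j] = 0.0
            continue
        ks[j] = stats.kstest(col, "norm", args=(col.mean(), sd)).statistic
    order = np.lexsort((np.arange(n_coef), -var, -ks))   # ks desc, var desc, index asc
    k = min(n_features, n_coef)
    # every wire contributes its best coefficient, so a unit confined to one
    # wire is never invisible in feature space; the rest fill up globally
    seeds: list[int] = []
    if n_ch > 1:
        for ch in range(n_ch):
            in_ch = order[channel_of[order] == ch]
            if in_ch.size:
                seeds.append(int(in_ch[0]))
        seeds.sort(key=lambda j: int(np.flatnonzero(order == j)[0]))   # by global rank
    chosen = seeds[:k]
    for j in order:
        if len(chosen) >= k:
            break
        if j not in chosen:
            chosen.append(int(j))
    sel = np.sort(np.asarray(chosen))
    return coeffs[:, sel], sel


def cluster_polytrode(
    features: np.ndarray,
    event_set: SpikeEventSet,
    params: ClusterParams | None = None,
) -> list[UnitCluster]:
    """Partition a polytrode group's events into units.

    The cluster count is selected by the algorithm, not fixed a priori:
    Gaussian mixtures with k = 1..k_max are fitted on the selected features
    and the best Bayesian information criterion wins.  Deterministic given
    the seed.
    """
    params = params or ClusterParams()
    n = event_set.n_events
    samples = np.array([e.sample for e in event_set.events])
    times = event_set.times_s
    if n == 0:
        return []
    if n < 2:
        labels = np.zeros(n, dtype=int)
    else:
        X = np.asarray(features, dtype=float)
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        best_bic, best_labels = np.inf, None
        for k in range(1, min(params.k_max, n) + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                random_state=params.seed,
                n_init=5,
                init_params="k-means++",
                reg_covar=1e-6,
            ).fit(X)
            bic = gm.bic(X)
            if bic < best_bic:
                best_bic, best_labels = bic, gm.predict(X)
        labels = best_labels

    clusters: list[UnitCluster] = []
    for cid in np.unique(labels):
        idx = np.flatnonzero(labels == cid)
        mean_wf = event_set.snippets[idx].mean(axis=0)
        p2p = np.ptp(mean_wf, axis=0)
        best_local = int(np.argmax(p2p))
        clusters.append(
            UnitCluster(
                cluster_id=int(cid),
                spike_times_s=times[idx],
                spike_samples=samples[idx],
                mean_waveform=mean_wf,
                features=np.asarray(features)[idx],
                group=event_set.group,
                best_channel=int(event_set.group_channels[best_local]),
            )
        )
    return clusters


def _isi_violation_frac(times_s: np.ndarray, violation_ms: float) -> float:
    if len(times_s) < 2:
        return 0.0
    isi = np.diff(np.sort(times_s))
    return float(np.mean(isi < violation_ms * 1e-3))


def merge_similar_clusters(
    clusters: list[UnitCluster],
    similarity_threshold: float = 0.95,
    isi_limit: float = 0.015,
    isi_violation_ms: float = 3.0,
) -> list[UnitCluster]:
    """Merge cluster pairs with near-identical mean waveforms.

    A pair merges when the Pearson correlation of their concatenated mean
    waveforms is at or above the threshold and the merged ISI-violation
    fraction stays within the acceptance limit.  Idempotent: a second pass
    changes nothing.
    """
    clusters = list(clusters)
    changed = True
    while changed and len(clusters) > 1:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                wa, wb = a.mean_waveform.ravel(), b.mean_waveform.ravel()
                if wa.std() == 0 or wb.std() == 0:
                    continue
                r = float(np.corrcoef(wa, wb)[0, 1])
                if r < similarity_threshold:
                    continue
                merged_times = np.sort(np.concatenate([a.spike_times_s, b.spike_times_s]))
                if _isi_violation_frac(merged_times, isi_violation_ms) > isi_limit:
                    continue
                order = np.argsort(np.concatenate([a.spike_samples, b.spike_samples]))
                samples = np.concatenate([a.spike_samples, b.spike_samples])[order]
                na, nb = a.n_spikes, b.n_spikes
                mean_wf = (a.mean_waveform * na + b.mean_waveform * nb) / (na + nb)
                p2p = np.ptp(mean_wf, axis=0)
                merged = UnitCluster(
                    cluster_id=a.cluster_id,
                    spike_times_s=merged_times,
                    spike_samples=samples,
                    mean_waveform=mean_wf,
                    features=np.vstack([a.features, b.features]),
                    group=a.group,
                    best_channel=a.best_channel if na >= nb else b.best_channel,
                )
                clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                clusters.append(merged)
                changed = True
                break
            if changed:
                break
    return clusters


def sort_recording(
    recording: ContinuousRecording,
    params: DetectionParams | None = None,
    cluster_params: ClusterParams | None = None,
) -> tuple[list[UnitCluster], ContinuousRecording, list[SpikeEventSet]]:
    """Full chain: filter → exclude broken → median-reference → detect →
    featurize → cluster → merge.  Returns (clusters, referenced recording,
    per-group event sets)."""
    params = params or DetectionParams()
    cluster_params = cluster_params or ClusterParams()
    filtered = bandpass(recording, params)
    mask = exclude_broken_channels(recording, params)
    referenced = median_reference_polytrode(filtered, mask)
    event_sets = detect_spikes(referenced, params, mask)
    clusters: list[UnitCluster] = []
    next_id = 0
    for es in event_sets:
        if es.n_events == 0:
            continue
        feats, _ = wavelet_features(
            es.snippets, cluster_params.n_features, cluster_params.wavelet
        )
        cl = cluster_polytrode(feats, es, cluster_params)
        cl = merge_similar_clusters(
            cl,
            cluster_params.merge_correlation,
            cluster_params.merge_isi_limit,
            cluster_params.isi_violation_ms,
        )
        for c in cl:
            c.cluster_id = next_id
            next_id += 1
        clusters.extend(cl)
    return clusters, referenced, event_sets
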