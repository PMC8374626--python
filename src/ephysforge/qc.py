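"""Single-unit acceptance criteria and quality metrics.

A sorted cluster is accepted as a single unit when its session firing rate
exceeds 0.5 Hz, fewer than 1.5% of inter-spike intervals fall below 3 ms,
its waveform looks like an action potential, and the cluster is distinct in
feature space.  Accepted units are summarized as per-region yield
(neurons/area) and efficiency (neurons/recording site), and characterized by
peak-to-peak SNR, waveform geometry and a putative excitatory/inhibitory
class from k-means on (width, afterhyperpolarization duration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .types import (
    EXCITATORY,
    INHIBITORY,
    OUTLIER,
    EventTable,
    SessionSummary,
    UnitCluster,
    UnitMetrics,
)

log = logging.getLogger(__name__)

# fallback reference centroids (width_ms, ahp_ms) when fewer than k units exist
_REF_INHIBITORY = (0.22, 0.25)
_REF_EXCITATORY = (0.58, 0.65)


@dataclass
class QCCriteria:
    """Acceptance thresholds for calling a cluster a single unit."""

    min_rate_hz: float = 0.5
    max_isi_violation_frac: float = 0.015
    isi_violation_ms: float = 3.0
    min_p2p_over_rms: float = 4.0      # waveform_ok heuristic
    min_silhouette: float = 0.2        # separation_ok heuristic

    def __post_init__(self) -> None:
        if self.min_rate_hz <= 0 or self.isi_violation_ms <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.max_isi_violation_frac <= 1:
            raise ValueError("max_isi_violation_frac must be in [0, 1]")


def isi_violation_fraction(spike_times_s: np.ndarray, violation_ms: float = 3.0) -> float:
    """Fraction of consecutive inter-spike intervals shorter than ``violation_ms``.

    Zero intervals (0 or 1 spikes) returns 0.0.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted ascending")
    if len(t) < 2:
        return 0.0
    isi = np.diff(t)
    return float(np.count_nonzero(isi < violation_ms * 1e-3) / len(isi))


def firing_rate(spike_times_s: np.ndarray, session_duration_s: float) -> float:
    """Mean rate: spike count over the whole session duration."""
    if session_duration_s <= 0:
        raise ValueError("session duration must be > 0")
    return len(spike_times_s) / session_duration_s


def residual_trace(
    trace: np.ndarray,
    spike_samples: np.ndarray,
    pre: int,
    post: int,
) -> np.ndarray:
    """Referenced trace of one channel with all detected spike windows excised."""
    keep = np.ones(len(trace), dtype=bool)
    for s in np.asarray(spike_samples, dtype=int):
        keep[max(s - pre, 0) : min(s + post, len(trace))] = False
    return trace[keep]


def compute_snr(mean_waveform: np.ndarray, residual: np.ndarray) -> float:
    """Peak-to-peak amplitude of the mean waveform over the RMS of the
    spike-free residual noise.

    For multi-channel mean waveforms the best (largest peak-to-peak) channel
    is used.
    """
    residual = np.asarray(residual, dtype=float)
    if residual.size == 0:
        raise ValueError("empty residual trace")
    w = np.asarray(mean_waveform, dtype=float)
    p2p = np.max(np.ptp(w, axis=0)) if w.ndim == 2 else np.ptp(w)
    rms = float(np.sqrt(np.mean(residual**2)))
    if rms == 0:
        return np.inf if p2p > 0 else 0.0
    return float(p2p / rms)


def waveform_features(
    mean_waveform: np.ndarray,
    sampling_rate_hz: float,
    ahp_fraction: float = 0.2,
) -> tuple[float, float, bool]:
    """(peak-to-trough width, afterhyperpolarization duration) in ms.

    Width is the time from the waveform trough to the subsequent positive
    peak.  The AHP duration is how long the post-peak tail stays above
    ``ahp_fraction`` (default 20%) of the peak amplitude.  Returns
    (width_ms, ahp_ms, outlier_flag); degenerate waveforms (flat, or no peak
    after the trough) are flagged as outliers with NaN features.
    """
    w = np.asarray(mean_waveform, dtype=float)
    if w.ndim == 2:
        w = w[:, int(np.argmax(np.ptp(w, axis=0)))]
    if np.ptp(w) == 0:
        return float("nan"), float("nan"), True
    trough = int(np.argmin(w))
    if trough >= len(w) - 1:
        return float("nan"), float("nan"), True
    after = w[trough:]
    peak_rel = int(np.argmax(after))
    peak = trough + peak_rel
    if peak_rel == 0 or w[peak] <= 0:
        return float("nan"), float("nan"), True
    width_ms = (peak - trough) / sampling_rate_hz * 1e3

    level = ahp_fraction * w[peak]
    below = np.flatnonzero(w[peak:] < level)
    ahp_samples = below[0] if below.size else len(w) - peak
    ahp_ms = ahp_samples / sampling_rate_hz * 1e3
    return float(width_ms), float(ahp_ms), False


def accept_unit(metrics: UnitMetrics, criteria: QCCriteria,
                waveform_ok: bool = True, separation_ok: bool = True) -> tuple[bool, list[str]]:
    """Conjunction of the four acceptance criteria; failures reported by name."""
    failed = []
    if not metrics.firing_rate_hz > criteria.min_rate_hz:
        failed.append("rate")
    if not metrics.isi_violation_frac < criteria.max_isi_violation_frac:
        failed.append("isi")
    if not waveform_ok:
        failed.append("waveform")
    if not separation_ok:
        failed.append("separation")
    return (len(failed) == 0), failed


def session_yield_efficiency(
    accepted_units: list[UnitMetrics],
    n_sites: int,
    session_id: str = "session",
) -> SessionSummary:
    """Per-region yield (accepted neurons/area) and efficiency
    (accepted neurons / recording site, 32 or 64)."""
    if n_sites not in (32, 64):
        raise ValueError("n_sites must be 32 or 64")
    per_region: dict[str, int] = {}
    for u in accepted_units:
        if not u.region:
            raise ValueError(f"unit {u.unit_id} has no region")
        per_region[u.region] = per_region.get(u.region, 0) + 1
    total = sum(per_region.values())
    return SessionSummary(
        session_id=session_id,
        yield_per_region=per_region,
        efficiency=total / n_sites,
        n_recording_sites=n_sites,
        n_accepted=total,
    )


def classify_ei(
    features: np.ndarray,
    k: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Putative excitatory / fast-spiking inhibitory / outlier labels.

    k-means with k=3 on (peak-to-trough width, AHP duration); the cluster
    with the smallest centroid on both features is inhibitory, the largest
    excitatory, the remainder outliers.  Units with NaN features are labeled
    outliers outright.  Deterministic given seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("features must be (n_units, 2): width_ms, ahp_ms")
    labels = np.full(len(X), OUTLIER, dtype=object)
    valid = np.all(np.isfinite(X), axis=1)
    Xv = X[valid]
    if len(Xv) == 0:
        return labels.astype(str)
    if len(Xv) < k:
        log.info("only %d units with features; nearest-reference-centroid fallback", len(Xv))
        ref = np.array([_REF_INHIBITORY, _REF_EXCITATORY])
        d = np.linalg.norm(Xv[:, None, :] - ref[None, :, :], axis=2)
        labels[valid] = np.where(d.argmin(axis=1) == 0, INHIBITORY, EXCITATORY)
        return labels.astype(str)

    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(Xv)
    sums = km.cluster_centers_.sum(axis=1)
    order = np.argsort(sums)                      # small → large centroid
    name_by_cluster = {order[0]: INHIBITORY, order[-1]: EXCITATORY}
    for c in order[1:-1]:
        name_by_cluster[c] = OUTLIER
    labels[valid] = np.array([name_by_cluster[c] for c in km.labels_], dtype=object)
    return labels.astype(str)


def psth_baseline_normalized(
    spike_times_s: np.ndarray,
    events: EventTable | np.ndarray,
    window_s: tuple[float, float] = (-0.5, 2.0),
    bin_ms: float = 50.0,
    baseline_ms: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged binned firing rate time-locked to events, with the mean
    rate over the first ``baseline_ms`` of the window subtracted.

    Returns (bin centers in s, baseline-normalized rate in Hz).
    """
    event_times = events.times_s if isinstance(events, EventTable) else np.asarray(events, float)
    if len(event_times) == 0:
        raise ValueError("no events to lock to")
    lo, hi = window_s
    bin_s = bin_ms * 1e-3
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    if len(edges) < 2:
        raise ValueError("window shorter than one bin")
    n_baseline = int(baseline_ms * 1e-3 / bin_s)   # whole bins only
    if n_baseline < 1:
        raise ValueError("baseline window contains no bins")

    t = np.asarray(spike_times_s, dtype=float)
    counts = np.zeros(len(edges) - 1)
    for ev in event_times:
        rel = t[(t >= ev + lo) & (t < ev + hi)] - ev
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(event_times) * bin_s)
    rate -= rate[:n_baseline].mean()
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, rate


def compare_region_timecourses(
    psth_a: np.ndarray,
    psth_b: np.ndarray,
    correct: bool = False,
) -> np.ndarray:
    """Per-bin paired two-sided t-test between two sets of unit PSTHs.

    Inputs are (n_units, n_bins) with units paired across the two sets.  No
    multiple-comparison correction by default; ``correct=True`` applies
    Benjamini–Hochberg.  Zero-variance (identical-pair) bins yield p = 1.
    """
    A = np.atleast_2d(np.asarray(psth_a, dtype=float))
    B = np.atleast_2d(np.asarray(psth_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("paired PSTH sets must have identical shape")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    diffs = A - B
    pvals = np.ones(A.shape[1])
    for j in range(A.shape[1]):
        d = diffs[:, j]
        if np.allclose(d.std(), 0.0):
            if not np.allclose(d, 0.0):
                log.info("bin %d: constant nonzero difference; p set to 1", j)
            continue
        pvals[j] = stats.ttest_rel(A[:, j], B[:, j]).pvalue
    if correct:
        pvals = _benjamini_hochberg(pvals)
    return pvals


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        adj[i] = prev
    return adj


def evaluate_units(
    clusters: list[UnitCluster],
    referenced_data: np.ndarray,
    sampling_rate_hz: float,
    duration_s: float,
    criteria: QCCriteria | None = None,
    snippet_pre: int = 20,
    snippet_post: int = 42,
    region_by_channel: dict[int, str] | None = None,
    seed: int = 0,
) -> list[UnitMetrics]:
    """Run the full QC battery over sorted clusters.

    SNR uses the referenced, band-passed trace of each unit's best channel
    with all of that channel's detected spike windows excised.
    """
    criteria = criteria or QCCriteria()
    all_samples = np.concatenate([c.spike_samples for c in clusters]) if clusters else np.array([])
    metrics: list[UnitMetrics] = []
    feats = []
    for c in clusters:
        rate = firing_rate(c.spike_times_s, duration_s)
        viol = isi_violation_fraction(np.sort(c.spike_times_s), criteria.isi_violation_ms)
        resid = residual_trace(
            referenced_data[:, c.best_channel], all_samples, snippet_pre, snippet_post
        )
        snr = compute_snr(c.mean_waveform, resid)
        width, ahp, outlier = waveform_features(c.mean_waveform, sampling_rate_hz)
        rms = float(np.sqrt(np.mean(resid**2))) if resid.size else 0.0
        w = c.mean_waveform
        p2p = float(np.max(np.ptp(w, axis=0))) if w.ndim == 2 else float(np.ptp(w))
        waveform_ok = (not outlier) and (rms == 0 or p2p >= criteria.min_p2p_over_rms * rms)
        m = UnitMetrics(
            unit_id=c.cluster_id,
            firing_rate_hz=rate,
            isi_violation_frac=viol,
            snr=snr,
            peak_to_trough_width_ms=width,
            hyperpolarization_ms=ahp,
            region=(region_by_channel or {}).get(c.best_channel, "unknown"),
        )
        m.accepted, m.failed_criteria = accept_unit(m, criteria, waveform_ok=waveform_ok)
        metrics.append(m)
        feats.append([width, ahp])
    if metrics:
        labels = classify_ei(np.asarray(feats, dtype=float), seed=seed)
        for m, lab in zip(metrics, labels):
            m.ei_class = lab
    return metrics
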