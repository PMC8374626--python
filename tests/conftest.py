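import numpy as np
import pytest

from ephysforge.sorting import ClusterParams, DetectionParams, sort_recording
from ephysforge.synthetic import generate_lfp_session, simulate_spike_session
from ephysforge.types import OscillationSpec, SimulationSpec


@pytest.fixture(scope="session")
def spike_session():
    """16-channel, one-bundle synthetic recording with 5 ground-truthed units."""
    spec = SimulationSpec(
        n_channels=16, duration_s=20.0, seed=11, noise_sd_uv=10.0,
        unit_rates_hz=(5.0,),
    )
    rec, gt = simulate_spike_session(spec, units_per_bundle=5)
    return rec, gt


@pytest.fixture(scope="session")
def sorted_session(spike_session):
    rec, gt = spike_session
    clusters, referenced, event_sets = sort_recording(
        rec, DetectionParams(), ClusterParams(seed=11)
    )
    return rec, gt, clusters, referenced, event_sets


@pytest.fixture(scope="session")
def lfp_session():
    """32-electrode event-locked LFP with one planted 20 Hz burst on electrode 5."""
    spec = SimulationSpec(
        n_channels=32, sampling_rate_hz=1000.0, noise_sd_uv=20.0,
        common_mode_amplitude_uv=50.0, artifact_trial_fraction=0.05, seed=21,
    )
    osc = [
        OscillationSpec(
            electrodes=[5], band="beta", center_hz=20.0,
            onset_s=0.2, offset_s=0.8, amplitude_uv=80.0,
        )
    ]
    rec, events, gt = generate_lfp_session(spec, osc, n_trials=40)
    return rec, events, gt


def match_clusters_to_truth(clusters, gt, tol_s=1e-3):
    """Per planted unit: (recall to its best cluster, purity of that cluster)."""
    out = {}
    for uid, times in gt.spike_times_per_unit.items():
        if len(times) == 0:
            continue
        best = None
        for c in clusters:
            if c.n_spikes == 0:
                continue
            hits = int(
                np.sum(np.min(np.abs(times[:, None] - c.spike_times_s[None, :]), axis=0) < tol_s)
            )
            if best is None or hits > best[1]:
                best = (c, hits)
        c, hits = best
        out[uid] = (hits / len(times), hits / c.n_spikes)
    return out
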