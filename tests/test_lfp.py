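"""LFP-chain contracts: epoching, artifact-trial rejection, median
referencing, Morlet decomposition, baseline handling, z-scoring and ICC."""

import numpy as np
import pandas as pd
import pytest

from ephysforge.lfp import (
    TFParams,
    average_by_trial_type,
    band_filter_trace,
    baseline_subtract,
    epoch,
    icc_2_1,
    median_reference,
    morlet_tf,
    reject_artifact_trials,
    session_icc,
    zscore_tf,
)
from ephysforge.types import ChannelMeta, ContinuousRecording, EpochedLFP, EventTable

FS = 1000.0


def _recording(data):
    meta = [ChannelMeta(index=i, bundle=0) for i in range(data.shape[1])]
    return ContinuousRecording(data=data, sampling_rate_hz=FS, channel_meta=meta)


def _events(times, types=None):
    times = np.asarray(times, dtype=float)
    return EventTable(frame=pd.DataFrame({
        "time_s": times,
        "trial_type": types if types is not None else ["go"] * len(times),
        "response_time_s": times + 0.5,
    }))


def _epochs(data, labels=None, referenced=False):
    n_trials, n_t, _ = data.shape
    return EpochedLFP(
        data=data,
        times_s=np.arange(n_t) / FS - 1.0,
        trial_labels=np.asarray(labels if labels is not None else ["go"] * n_trials),
        sampling_rate_hz=FS,
        referenced=referenced,
    )


class TestEpoch:
    def test_shape(self):
        rec = _recording(np.zeros((500_000, 4)))
        ep = epoch(rec, _events(np.arange(2.0, 400.0, 4.0)), (-1.0, 2.0))
        assert ep.data.shape == (100, 3000, 4)

    def test_out_of_range_event_dropped(self):
        rec = _recording(np.zeros((10_000, 2)))
        ep = epoch(rec, _events([0.1, 5.0]), (-1.0, 2.0))
        assert ep.n_trials == 1

    def test_lock_column_shifts_axis_only(self):
        rng = np.random.default_rng(0)
        rec = _recording(rng.normal(size=(20_000, 2)))
        ev = _events([5.0, 10.0])
        a = epoch(rec, ev, (-1.0, 2.0), lock="time_s")
        b = epoch(rec, ev, (-1.0, 2.0), lock="response_time_s")
        np.testing.assert_allclose(a.data[:, 500:, :], b.data[:, :-500, :])

    def test_no_usable_events_rejected(self):
        rec = _recording(np.zeros((1000, 2)))
        with pytest.raises(ValueError, match="no usable events"):
            epoch(rec, _events([0.1]), (-1.0, 2.0))


class TestArtifactRejection:
    def test_hand_arithmetic_case(self):
        rng = np.random.default_rng(0)
        sds = [1.0, 1.0, 1.0, 1.0, 20.0]
        data = np.stack([rng.normal(0, s, size=(1000, 3)) for s in sds])
        rejected = reject_artifact_trials(_epochs(data), artifact_k=4.0)
        np.testing.assert_array_equal(rejected, [False, False, False, False, True])

    def test_homogeneous_trials_none_rejected(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 1000, 3))
        assert not reject_artifact_trials(_epochs(data)).any()

    def test_electrode_permutation_invariant(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(10, 500, 8))
        data[3] *= 10
        a = reject_artifact_trials(_epochs(data))
        b = reject_artifact_trials(_epochs(data[:, :, rng.permutation(8)]))
        np.testing.assert_array_equal(a, b)

    def test_planted_artifacts_flagged(self, lfp_session):
        rec, events, gt = lfp_session
        ep = epoch(rec, events, (-1.0, 2.0))
        rejected = np.flatnonzero(reject_artifact_trials(ep))
        assert set(gt.artifact_trials) <= set(rejected)

    def test_runs_only_before_referencing(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 100, 4))
        with pytest.raises(ValueError, match="before median referencing"):
            reject_artifact_trials(_epochs(data, referenced=True))


class TestMedianReference:
    def test_identical_signal_zeroed(self):
        sig = np.sin(np.linspace(0, 20, 3000))
        data = np.tile(sig[None, :, None], (4, 1, 8))
        out = median_reference(_epochs(data))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_pairwise_differences_preserved(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 500, 8))
        out = median_reference(_epochs(data))
        np.testing.assert_allclose(
            out.data[..., 1:] - out.data[..., :-1],
            data[..., 1:] - data[..., :-1],
            atol=1e-10,
        )

    def test_double_referencing_guarded(self):
        data = np.zeros((2, 100, 4))
        out = median_reference(_epochs(data))
        with pytest.raises(ValueError, match="already"):
            median_reference(out)


class TestMorletTF:
    def _tone_epochs(self, freq, amp=1.0, n_trials=2, n_e=2):
        t = np.arange(4000) / FS
        sig = amp * np.sin(2 * np.pi * freq * t)
        data = np.tile(sig[None, :, None], (n_trials, 1, n_e))
        ep = _epochs(data, referenced=True)
        ep.times_s = t - 1.0
        return ep

    @pytest.mark.parametrize("freq", [5.0, 10.0, 40.0])
    def test_tone_localizes_to_nearest_bin(self, freq):
        params = TFParams()
        tf = morlet_tf(self._tone_epochs(freq), params)
        mid = np.nanmean(tf.data[0, :, :, 0], axis=0)
        assert tf.freqs_hz[np.nanargmax(mid)] == pytest.approx(
            tf.freqs_hz[np.argmin(np.abs(tf.freqs_hz - freq))]
        )

    def test_amplitude_linearity(self):
        params = TFParams()
        a = morlet_tf(self._tone_epochs(10.0, amp=1.0), params)
        b = morlet_tf(self._tone_epochs(10.0, amp=2.0), params)
        fi = np.argmin(np.abs(a.freqs_hz - 10.0))
        ratio = np.nanmean(b.data[0, :, fi, 0]) / np.nanmean(a.data[0, :, fi, 0])
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_cycles_convention_closed_form(self):
        params = TFParams()
        assert params.cycles_at(70.0) == pytest.approx(2 * (70 / 2) ** 0.3, rel=1e-12)
        assert params.cycles_at(2.0) == pytest.approx(2.0)

    def test_amplitude_nonnegative_and_edges_nan(self):
        tf = morlet_tf(self._tone_epochs(10.0), TFParams())
        assert np.nanmin(tf.data) >= 0
        assert np.isnan(tf.data[0, 0, 0, 0])    # lowest-frequency edge

    def test_unreferenced_epochs_rejected(self):
        ep = self._tone_epochs(10.0)
        ep.referenced = False
        with pytest.raises(ValueError, match="reference"):
            morlet_tf(ep, TFParams())

    def test_window_too_short_names_minimum(self):
        data = np.zeros((1, 300, 2))
        ep = _epochs(data, referenced=True)
        with pytest.raises(ValueError, match="at least"):
            morlet_tf(ep, TFParams())

    def test_white_noise_power_monotone_in_variance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 4000, 1))
        powers = []
        for scale in (1.0, 2.0, 4.0):
            ep = _epochs(base * scale, referenced=True)
            tf = morlet_tf(ep, TFParams(n_freqs=10))
            powers.append(np.nansum(tf.data**2))
        assert powers[0] < powers[1] < powers[2]


class TestBaselineAndAveraging:
    def _tf(self, n_trials=4, labels=None):
        rng = np.random.default_rng(0)
        from ephysforge.types import TFTensor

        return TFTensor(
            data=rng.normal(10, 1, size=(n_trials, 50, 6, 3)),
            times_s=np.linspace(-1, 2, 50),
            freqs_hz=np.linspace(2, 70, 6),
            trial_labels=np.asarray(labels if labels is not None else ["go"] * n_trials),
        )

    def test_stationary_residual_near_zero(self):
        tf = self._tf()
        out = baseline_subtract(tf, (-0.5, 0.0))
        assert abs(np.nanmean(out.data)) < 0.5

    def test_double_subtraction_guarded(self):
        out = baseline_subtract(self._tf(), (-0.5, 0.0))
        with pytest.raises(ValueError, match="raw"):
            baseline_subtract(out, (-0.5, 0.0))

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            baseline_subtract(self._tf(), (-10.0, -5.0))

    def test_single_trial_average_is_identity(self):
        tf = self._tf(3, labels=["go", "wait", "wait"])
        out = average_by_trial_type(tf)
        np.testing.assert_array_equal(out["go"].data, tf.data[0])

    def test_type_without_trials_omitted(self):
        tf = self._tf(2, labels=["go", "go"])
        out = average_by_trial_type(tf, trial_types=["go", "wait"])
        assert set(out) == {"go"}

    def test_rejected_trials_excluded(self):
        tf = self._tf(4)
        rejected = np.array([False, True, False, False])
        out = average_by_trial_type(tf, rejected=rejected)
        np.testing.assert_allclose(out["go"].data, tf.data[[0, 2, 3]].mean(axis=0))


class TestZScore:
    def _avg_tf(self):
        rng = np.random.default_rng(1)
        from ephysforge.types import TFTensor

        return TFTensor(
            data=rng.normal(5, 2, size=(100, 6, 3)),
            times_s=np.linspace(-1, 2, 100),
            freqs_hz=np.linspace(2, 70, 6),
        )

    def test_slices_mean_zero_sd_one(self):
        z = zscore_tf(self._avg_tf())
        np.testing.assert_allclose(np.nanmean(z.data, axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(np.nanstd(z.data, axis=0), 1.0, atol=1e-8)

    def test_constant_slice_zeroed_and_flagged(self):
        tf = self._avg_tf()
        tf.data[:, 2, 1] = 7.0
        z = zscore_tf(tf)
        np.testing.assert_array_equal(z.data[:, 2, 1], 0.0)
        assert z.degenerate_slices[2, 1]

    def test_idempotent(self):
        z1 = zscore_tf(self._avg_tf())
        z2 = zscore_tf(z1)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-12)


class TestICC:
    def test_identical_sessions_icc_one(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(20, 5, 3))
        res = session_icc([s, s.copy(), s.copy()])
        np.testing.assert_allclose(res.icc, 1.0, atol=1e-12)

    def test_independent_noise_icc_near_zero(self):
        rng = np.random.default_rng(1)
        sessions = [rng.normal(size=(100, 100, 2)) for _ in range(5)]
        res = session_icc(sessions)
        assert np.abs(res.icc).max() < 0.05

    def test_matches_anova_oracle(self):
        """ICC(2,1) equals the independent two-way ANOVA implementation."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        for _ in range(5):
            Y = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
            n, k = Y.shape
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": Y.ravel(),
            })
            ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                     ratings="score")
            sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
            ref_icc2 = float(ref.loc[sel, "ICC"].iloc[0])
            assert icc_2_1(Y) == pytest.approx(ref_icc2, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            session_icc([np.zeros((5, 2, 2)), np.zeros((4, 2, 2))])


class TestBandFilter:
    def test_passband_preserved(self):
        t = np.arange(8000) / FS
        data = np.sin(2 * np.pi * 12 * t)[None, :, None]
        out = band_filter_trace(_epochs(data), (8.0, 20.0))
        mid = out[0, 2000:-2000, 0]
        assert (mid.max() - mid.min()) / 2 == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        t = np.arange(8000) / FS
        data = np.sin(2 * np.pi * 2 * t)[None, :, None]
        out = band_filter_trace(_epochs(data), (8.0, 20.0))
        assert np.abs(out[0, 2000:-2000, 0]).max() < 0.1

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            band_filter_trace(_epochs(np.zeros((1, 100, 2))), (100.0, 600.0))


class TestPlantedBurstRecovery:
    def test_burst_localized_and_confined(self, lfp_session):
        """A 20 Hz burst planted on electrode 5 appears at the nearest
        frequency bin on that electrode and nowhere else after referencing."""
        rec, events, gt = lfp_session
        ep = epoch(rec, events, (-1.0, 2.0))
        rejected = reject_artifact_trials(ep)
        ep = median_reference(ep)
        params = TFParams()
        tf = morlet_tf(ep, params)
        tf = baseline_subtract(tf, (-0.5, 0.0))
        avg = average_by_trial_type(tf, rejected=rejected)
        combined = np.nanmean(
            np.stack([v.data for v in avg.values()]).mean(axis=0), axis=None
        )  # smoke: finite
        assert np.isfinite(combined)
        grand = sum(v.data * 1.0 for v in avg.values()) / len(avg)
        window = (tf.times_s >= 0.3) & (tf.times_s <= 0.7)
        spectrum_e5 = np.nanmean(grand[window][:, :, 5], axis=0)
        peak_freq = tf.freqs_hz[np.nanargmax(spectrum_e5)]
        nearest = tf.freqs_hz[np.argmin(np.abs(tf.freqs_hz - 20.0))]
        assert peak_freq == pytest.approx(nearest)
        others = np.delete(np.arange(ep.n_electrodes), 5)
        fi = np.argmin(np.abs(tf.freqs_hz - 20.0))
        burst_amp = np.nanmean(grand[window][:, fi, 5])
        other_amp = np.nanmean(grand[window][:, fi, others])
        assert burst_amp > 5 * abs(other_amp)
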