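"""Coregistration chain: fixation parsing, filtering, epoching, rejection."""

import numpy as np
import pytest
from scipy.signal import butter, freqz

from frpsonet.preprocess import (PreprocConfig, bandpass, baseline_correct,
                                 detect_fixations, epoch_trials,
                                 preprocess_recording, reject_artifacts,
                                 resample_epochs, validate_fixations)
from frpsonet.preprocess import FixationEvent
from frpsonet.synth import SynthConfig, synth_session

FS = 500.0


class TestDetectFixations:
    def test_stationary_trace_is_one_fixation(self):
        gaze = np.full((400, 2), 1.5)
        events = detect_fixations(gaze, FS)
        assert len(events) == 1
        assert events[0].onset_sample == 0
        assert events[0].duration_ms == pytest.approx(400 / FS * 1000)

    def test_two_segments_split_by_saccade(self):
        # 200 deg/s saccade between two stationary segments: at 500 Hz the
        # displacement is 0.4 deg/sample, far above both thresholds
        a = np.zeros((300, 2))
        step = np.linspace(0, 8.0, 21)[1:-1]  # 200 deg/s for 40 ms
        sacc = np.stack([step, np.zeros_like(step)], axis=1)
        b = np.full((300, 2), (8.0, 0.0))
        gaze = np.concatenate([a, sacc, b])
        # hand-computed velocity: within segments 0 deg/s, inside saccade 200 deg/s
        events = detect_fixations(gaze, FS)
        assert len(events) == 2
        assert events[0].onset_sample == 0
        assert abs(events[1].centroid[0] - 8.0) < 0.05

    def test_everywhere_fast_trace_has_no_fixations(self):
        t = np.arange(200) / FS
        gaze = np.stack([100.0 * t, np.zeros_like(t)], axis=1)  # 100 deg/s drift
        assert detect_fixations(gaze, FS) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            detect_fixations(np.zeros((1, 2)), FS)

    def test_dispersion_splits_slow_drift(self):
        # slow drift below the velocity threshold but exceeding 0.15 deg total
        t = np.arange(1000) / FS
        gaze = np.stack([0.5 * t, np.zeros_like(t)], axis=1)  # 0.5 deg/s
        events = detect_fixations(gaze, FS)
        assert len(events) > 1


class TestValidateFixations:
    trials = [(0, 1000, (0.0, 0.0))]

    def _fix(self, duration_ms=400.0, centroid=(1.0, 0.0)):
        return FixationEvent(onset_sample=10, duration_ms=duration_ms,
                             centroid=centroid)

    def test_short_fixation_rejected(self):
        assert validate_fixations([self._fix(duration_ms=300.0)], self.trials) == []

    def test_off_circle_fixation_rejected(self):
        assert validate_fixations([self._fix(centroid=(4.0, 0.0))], self.trials) == []

    def test_valid_fixation_kept(self):
        kept = validate_fixations([self._fix()], self.trials)
        assert len(kept) == 1 and kept[0][0] == 0

    def test_only_first_valid_fixation_per_trial(self):
        early = FixationEvent(onset_sample=5, duration_ms=400, centroid=(0.5, 0))
        late = FixationEvent(onset_sample=500, duration_ms=400, centroid=(0.1, 0))
        kept = validate_fixations([late, early], self.trials)
        assert len(kept) == 1
        assert kept[0][1].onset_sample == 5


class TestBandpass:
    fs = 1000.0

    def test_dc_removed(self):
        x = np.full((2, 4000), 10.0)
        y = bandpass(x, self.fs)
        assert np.abs(y[:, 1000:3000]).max() < 0.1  # < 1% of input

    @pytest.mark.parametrize("freq, check", [(10.0, "pass"), (60.0, "stop")])
    def test_amplitude_matches_analytic_response(self, freq, check):
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * freq * t)[None, :]
        y = bandpass(x, self.fs)[0, 2000:6000]
        measured = y.max()
        # independent oracle: squared Butterworth magnitude (filtfilt = |H|^2)
        b, a = butter(2, (1.0, 40.0), btype="bandpass", fs=self.fs)
        _, h = freqz(b, a, worN=[freq], fs=self.fs)
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=0.02)
        if check == "pass":
            assert abs(measured - 1.0) < 0.05
        else:
            assert measured < 0.5

    def test_zero_phase(self):
        t = np.arange(4000) / self.fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        y = bandpass(x, self.fs)
        xc = np.correlate(y[0, 1000:3000], x[0, 1000:3000], mode="full")
        assert xc.argmax() == len(xc) // 2  # peak at zero lag

    def test_nonfinite_rejected(self):
        x = np.zeros((1, 100))
        x[0, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            bandpass(x, self.fs)


class TestEpoching:
    fs = 1000.0

    def test_epoch_length_1200_samples(self):
        eeg = np.random.default_rng(0).standard_normal((3, 5000))
        epochs, kept = epoch_trials(eeg, np.array([1000]), self.fs)
        assert epochs.shape == (1, 3, 1200)
        assert kept.all()

    def test_zero_onsets_zero_epochs(self):
        epochs, kept = epoch_trials(np.zeros((3, 1000)), np.array([], dtype=int), self.fs)
        assert epochs.shape[0] == 0

    def test_onset_near_edge_dropped(self):
        epochs, kept = epoch_trials(np.zeros((2, 3000)), np.array([50, 1000]), self.fs)
        assert epochs.shape[0] == 1
        assert list(kept) == [False, True]

    def test_t0_sample_alignment(self):
        eeg = np.zeros((1, 4000))
        eeg[0, 2000] = 1.0
        epochs, _ = epoch_trials(eeg, np.array([2000]), self.fs)
        assert epochs[0, 0, 200] == 1.0  # 200 ms pre-window -> index 200


class TestBaseline:
    fs = 1000.0

    def test_constant_epoch_becomes_zero(self):
        epochs = np.full((1, 2, 1200), 7.0)
        np.testing.assert_allclose(baseline_correct(epochs, self.fs), 0.0, atol=1e-12)

    def test_zero_mean_baseline_unchanged(self):
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((2, 3, 1200))
        epochs -= epochs[..., :100].mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(baseline_correct(epochs, self.fs), epochs, atol=1e-12)

    def test_ramp_shifted_by_its_baseline_mean(self):
        ramp = np.arange(1200, dtype=float)[None, None, :]
        out = baseline_correct(ramp, self.fs)
        np.testing.assert_allclose(out, ramp - ramp[..., :100].mean(), atol=1e-10)

    def test_post_hoc_baseline_mean_is_zero(self):
        rng = np.random.default_rng(2)
        out = baseline_correct(rng.standard_normal((4, 2, 1200)), self.fs)
        np.testing.assert_allclose(out[..., :100].mean(axis=-1), 0.0, atol=1e-10)


class TestArtifactRejection:
    fs = 1000.0

    def test_large_step_rejected(self):
        epochs = np.zeros((1, 2, 1200))
        epochs[0, 0, 600:] = 120.0
        assert not reject_artifacts(epochs, self.fs)[0]

    def test_clean_epoch_kept(self):
        assert reject_artifacts(np.zeros((1, 2, 1200)), self.fs)[0]

    def test_exact_threshold_swing_kept(self):
        epochs = np.zeros((1, 1, 1200))
        epochs[0, 0, 600:] = 100.0  # exactly 100 uV: not *surpassing*
        assert reject_artifacts(epochs, self.fs)[0]

    def test_final_partial_window_checked(self):
        epochs = np.zeros((1, 1, 1210))
        epochs[0, 0, -3] = 150.0  # transient only in the trailing partial window
        assert not reject_artifacts(epochs, self.fs)[0]


class TestResampling:
    fs = 1000.0

    def test_one_second_gives_128_samples(self):
        out = resample_epochs(np.zeros((2, 3, 1200)), self.fs)
        assert out.shape == (2, 3, 128)

    def test_sinusoid_preserved(self):
        t = np.arange(-200, 1000) / self.fs
        x = np.sin(2 * np.pi * 5.0 * t)[None, None, :]
        out = resample_epochs(x, self.fs)[0, 0]
        t_new = np.arange(128) / 128.0
        ref = np.sin(2 * np.pi * 5.0 * t_new)
        rms = np.sqrt(np.mean((out - ref) ** 2)) / np.sqrt(np.mean(ref ** 2))
        assert rms < 0.02

    def test_zero_in_zero_out(self):
        assert np.all(resample_epochs(np.zeros((1, 1, 1200)), self.fs) == 0.0)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="fs_out"):
            resample_epochs(np.zeros((1, 1, 1200)), 64.0)


@pytest.fixture(scope="module")
def session():
    return synth_session(SynthConfig(seed=17, noise_sd=6.0), 20)


class TestFullChain:

    def test_clean_session_retains_all_trials(self, session):
        ts = preprocess_recording(session)
        assert ts.n_trials == 20
        assert ts.data.shape == (20, 19, 128)
        assert int(ts.labels.sum()) == int(round(20 * 0.12))

    def test_injected_transient_removes_exactly_that_epoch(self, session):
        rec = synth_session(SynthConfig(seed=17, noise_sd=6.0), 20)
        k = 4
        onset = rec.events[k][0]
        rec.eeg[3, onset + 300:onset + 315] += 400.0  # 400 uV transient in epoch k
        ts = preprocess_recording(rec)
        assert ts.n_trials == 19
        clean = preprocess_recording(session)
        expected = np.delete(clean.labels, k)
        np.testing.assert_array_equal(ts.labels, expected)

    def test_chain_deterministic(self, session):
        a = preprocess_recording(session)
        b = preprocess_recording(session)
        np.testing.assert_array_equal(a.data, b.data)

    def test_filter_epoch_commutes_for_interior_epochs(self, session):
        cfg = PreprocConfig()
        onset = session.events[10][0]
        filtered = bandpass(session.eeg, session.fs, cfg)
        a, _ = epoch_trials(filtered, np.array([onset]), session.fs, cfg)
        # epoch a generous context first, then filter and crop
        wide = session.eeg[:, onset - 2200:onset + 3000]
        b = bandpass(wide, session.fs, cfg)[:, 2000:3200]
        rms = np.sqrt(np.mean((a[0] - b) ** 2))
        assert rms < 1.0  # uV
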