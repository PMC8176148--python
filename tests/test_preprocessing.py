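"""Filtering, notch, ICA artifact attenuation, epoching and rejection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from megconn.preprocessing import (
    PreprocConfig,
    SensorRecording,
    bandpass_butterworth,
    epoch,
    ica_attenuate,
    notch,
    reject_epochs,
)
from megconn.synthetic import ArtifactModel, inject_artifacts

FS = 600.0


def make_recording(data, trace=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if trace is None:
        trace = np.zeros((data.shape[1], 3))
    return SensorRecording(data=data, sampling_rate=FS,
                           head_position_trace=trace, subject_id="t")


def sine(freq, seconds=20.0, amp=1.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestButterworth:
    def test_matches_two_pass_transfer_function_oracle(self):
        """Measured attenuation agrees with |H(f)|^2 of the order-4
        design evaluated independently; 0.1 Hz is suppressed > 20 dB
        while 10 Hz passes within 5%."""
        sos = signal.butter(4, [1, 150], btype="band", output="sos", fs=FS)
        for freq, check in [(0.1, "stop"), (10.0, "pass")]:
            _, h = signal.sosfreqz(sos, worN=[freq], fs=FS)
            expected_gain = np.abs(h[0]) ** 2  # forward-backward squares |H|
            x = sine(freq, seconds=60.0)
            y = bandpass_butterworth(make_recording(x)).data[0]
            mid = slice(int(10 * FS), int(50 * FS))  # avoid edge transients
            measured = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
            if check == "stop":
                assert measured < 10 ** (-20 / 20)
                assert measured == pytest.approx(expected_gain, rel=0.2)
            else:
                assert abs(measured - 1) < 0.05
                assert measured == pytest.approx(expected_gain, rel=0.01)

    def test_zero_input_zero_output(self):
        out = bandpass_butterworth(make_recording(np.zeros((3, 6000))))
        np.testing.assert_allclose(out.data, 0.0)

    def test_invalid_cutoffs_rejected(self):
        rec = make_recording(sine(10))
        with pytest.raises(ValueError):
            bandpass_butterworth(rec, 1.0, 400.0)  # above Nyquist
        with pytest.raises(ValueError):
            bandpass_butterworth(rec, 10.0, 5.0)

    def test_passband_idempotence(self):
        # content well inside 1-150 Hz is unchanged by a second pass
        raw = np.random.default_rng(0).standard_normal((2, 12000))
        inband = signal.filtfilt(*signal.butter(4, [5, 100], btype="band", fs=FS),
                                 raw, axis=-1)
        once = bandpass_butterworth(make_recording(inband))
        twice = bandpass_butterworth(once)
        mid = slice(1200, 10800)
        assert np.corrcoef(once.data[0, mid], twice.data[0, mid])[0, 1] > 0.999
        assert once.data.shape == inband.shape


class TestNotch:
    def test_line_frequency_suppressed(self):
        x = sine(60.0)
        y = notch(make_recording(x)).data[0]
        assert np.sqrt(np.mean(y**2)) < 0.03 * np.sqrt(np.mean(x**2))

    def test_neighbouring_frequencies_untouched(self):
        x = sine(10.0)
        y = notch(make_recording(x)).data[0]
        assert np.abs(y - x).max() < 0.01 * np.abs(x).max()
        # 5 Hz away from the line: attenuation below 1 dB
        x55 = sine(55.0)
        y55 = notch(make_recording(x55)).data[0]
        ratio = np.sqrt(np.mean(y55**2) / np.mean(x55**2))
        assert ratio > 10 ** (-1 / 20)

    def test_both_harmonics_attenuated(self):
        x = sine(60.0) + sine(120.0)
        y = notch(make_recording(x)).data[0]
        spec = np.abs(np.fft.rfft(y))
        grid = np.fft.rfftfreq(len(y), 1 / FS)
        for f0 in (60.0, 120.0):
            assert spec[np.argmin(np.abs(grid - f0))] < 1e-6 * len(y)


class TestICA:
    def _blinky_recording(self, rng, n_ch=15, seconds=60.0, amp=40.0):
        # envelope-modulated band noise: leptokurtic, hence ICA-identifiable
        # (band-limited Gaussian sources would not be)
        n = int(seconds * FS)
        carriers = signal.filtfilt(*signal.butter(4, [2, 40], btype="band", fs=FS),
                                   rng.standard_normal((5, n)), axis=-1)
        envelopes = np.abs(
            signal.filtfilt(*signal.butter(2, 0.4, btype="low", fs=FS),
                            rng.standard_normal((5, n)), axis=-1)
        )
        sources = carriers * envelopes / (carriers * envelopes).std(axis=-1, keepdims=True)
        mixing = rng.standard_normal((n_ch, 5))
        course = np.zeros(n)
        for c in range(600, n - 600, 2400):  # periodic blink bumps
            course[c : c + 180] += np.hanning(180)
        topo = np.linspace(1, 0.05, n_ch)
        data = mixing @ sources + amp * np.outer(topo, course)
        data += 0.01 * rng.standard_normal(data.shape)  # keep mixture full rank
        return make_recording(data), course

    def test_blink_component_removed(self, rng):
        rec, course = self._blinky_recording(rng)
        cleaned, report = ica_attenuate(rec, {"blink": course}, n_components=6,
                                        random_state=1)
        assert report["status"] == "ok"
        assert len(report["removed"]) >= 1
        worst = max(abs(np.corrcoef(ch, course)[0, 1]) for ch in cleaned.data)
        assert worst < 0.1

    def test_no_templates_is_identity(self, rng):
        rec, _ = self._blinky_recording(rng)
        out, report = ica_attenuate(rec, None)
        assert out is rec and report["removed"] == []

    def test_artifact_free_recording_unchanged(self, rng):
        n = int(60 * FS)
        data = signal.filtfilt(*signal.butter(4, [2, 40], btype="band", fs=FS),
                               rng.standard_normal((10, n)), axis=-1)
        rec = make_recording(data)
        template = rng.standard_normal(n)  # unrelated to any component
        out, report = ica_attenuate(rec, {"noise": template}, n_components=6,
                                    random_state=2)
        assert report["removed"] == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_injected_cardiac_recovered_by_ica(self, rng):
        """A dominant cardiac artifact appears as one ICA component
        whose time course correlates > 0.9 with the injected course."""
        n = int(60 * FS)
        brain = signal.filtfilt(*signal.butter(4, [2, 40], btype="band", fs=FS),
                                rng.standard_normal((12, n)), axis=-1) * 20
        rec = make_recording(brain)
        model = ArtifactModel(ocular_amplitude=0.0, cardiac_amplitude=2000.0,
                              n_jumps=0, excursion_probability=0.0)
        noisy, truth = inject_artifacts(rec, model, rng)
        from sklearn.decomposition import FastICA

        S = FastICA(n_components=8, whiten="unit-variance",
                    random_state=0, max_iter=500).fit_transform(noisy.data.T)
        best = max(abs(np.corrcoef(S[:, k], truth["cardiac"])[0, 1]) for k in range(8))
        assert best > 0.9


class TestEpoching:
    def test_exact_division(self):
        rec = make_recording(np.ones((2, int(300 * FS))))
        assert epoch(rec, 10.0).epochs.shape == (30, 2, 6000)

    def test_trailing_remainder_dropped(self):
        rec = make_recording(np.ones((2, int(305 * FS))))
        assert epoch(rec, 10.0).n_epochs == 30

    def test_too_short_recording_is_empty_with_warning(self):
        rec = make_recording(np.ones((2, int(9 * FS))))
        with pytest.warns(UserWarning):
            out = epoch(rec, 10.0)
        assert out.n_epochs == 0

    @given(seconds=st.integers(min_value=10, max_value=120))
    @settings(max_examples=20, deadline=None)
    def test_epoch_count_is_floor_of_duration(self, seconds):
        rec = make_recording(np.zeros((1, int(seconds * FS))))
        assert epoch(rec, 10.0).n_epochs == seconds // 10


class TestRejection:
    def _epoched(self, data, trace):
        return reject_epochs(epoch(make_recording(data, trace), 10.0), trace)

    def test_motion_epoch_rejected(self, rng):
        n = 3 * 6000
        trace = np.zeros((n, 3))
        trace[7000:8000, 0] = 12.0  # 12 mm excursion in epoch 1
        out = self._epoched(rng.normal(0, 100, (2, n)), trace)
        assert out.flags == ["none", "motion", "none"]

    def test_jump_epoch_rejected(self, rng):
        n = 2 * 6000
        data = rng.normal(0, 100, (3, n))
        data[1, 9000:] += 2500.0
        out = self._epoched(data, np.zeros((n, 3)))
        assert out.flags == ["none", "jump"]

    def test_clean_epoch_retained(self, rng):
        n = 6000
        trace = np.zeros((n, 3))
        trace[:, 1] = 2.0 * np.sin(np.linspace(0, 3, n))  # max 2 mm
        out = self._epoched(rng.normal(0, 100, (2, n)), trace)
        assert out.flags == ["none"]
        assert out.head_motion == pytest.approx(out.epoch_displacement[0])

    def test_jump_sensitivity_at_and_above_threshold(self, rng):
        """Steps >= 1.25x the 2000 fT threshold are always flagged."""
        for amp in (2500.0, 3000.0, 5000.0):
            n = 12000
            data = rng.normal(0, 100, (4, n))
            ch = int(rng.integers(0, 4))
            data[ch, 3000:] += amp
            out = self._epoched(data, np.zeros((n, 3)))
            assert out.flags[0] == "jump"

    def test_head_motion_covariate_over_retained_epochs_only(self, rng):
        n = 3 * 6000
        trace = np.zeros((n, 3))
        trace[:6000, 0] = 1.0
        trace[6000:12000, 0] = 1.5
        trace[12000:, 0] = 20.0  # epoch 2 rejected for motion
        out = self._epoched(rng.normal(0, 10, (3, n)), trace)
        assert out.flags == ["none", "none", "motion"]
        # covariate = mean max displacement of the retained epochs, measured
        # from the whole-recording median position
        assert out.head_motion == pytest.approx(np.mean(out.epoch_displacement[:2]))
        assert out.head_motion < 1.0  # rejected epoch excluded


def test_full_preprocess_chain_runs(rng):
    from megconn.preprocessing import preprocess

    n = int(30 * FS)
    data = signal.filtfilt(*signal.butter(4, [2, 40], btype="band", fs=FS),
                           rng.standard_normal((8, n)), axis=-1) * 50
    trace = np.zeros((n, 3))
    rec = SensorRecording(data=data, sampling_rate=FS,
                          head_position_trace=trace, subject_id="t")
    epoched, report = preprocess(rec, PreprocConfig(ica_n_components=4))
    assert epoched.n_epochs == 3
    assert set(epoched.flags) <= {"none", "motion", "jump"}
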