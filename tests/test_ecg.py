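import numpy as np
import pytest

import hprglm as h
from hprglm.exceptions import (
    ArgumentError,
    ConfigurationError,
    NoQRSDetectedError,
)
from hprglm.series import FLAG_CORRECTED, FLAG_OK, FLAG_OUTLIER


class TestAntialiasDownsample:
    def test_dc_passes_unchanged(self):
        ecg = h.ECGSignal(np.full(5000, 0.7), fs=1000.0)
        out = h.antialias_downsample(ecg)
        assert out.fs == 200.0
        assert np.allclose(out.samples, 0.7, atol=1e-9)

    def test_sample_count_follows_rate_ratio(self):
        n = 12345
        ecg = h.ECGSignal(np.zeros(n), fs=1000.0)
        out = h.antialias_downsample(ecg)
        assert out.samples.size == round(n / 5)

    def test_40hz_sine_attenuated_by_butterworth_response(self):
        # Second-order Butterworth low-pass at fc = 100 Hz, applied
        # zero-phase (forward-backward), so the amplitude gain is |H|^2
        # with |H|^2 = 1 / (1 + (tan(pi f/fs) / tan(pi fc/fs))^4) — the
        # closed-form Butterworth magnitude under the bilinear frequency
        # mapping of a digital design (the analog form 1/(1 + (f/fc)^4)
        # differs by < 0.3% at this frequency).
        fs, f = 1000.0, 40.0
        t = np.arange(int(10 * fs)) / fs
        ecg = h.ECGSignal(np.sin(2 * np.pi * f * t), fs=fs)
        out = h.antialias_downsample(ecg)
        ratio = np.tan(np.pi * f / fs) / np.tan(np.pi * 100.0 / fs)
        expected = 1.0 / (1.0 + ratio**4)
        # RMS-based amplitude: robust to where the 200 Hz grid samples
        # the sine's peaks.
        core = out.samples[200:-200]
        measured = np.sqrt(2.0) * np.sqrt(np.mean(core**2))
        assert abs(measured - expected) < 0.01

    def test_low_rate_rejected(self):
        with pytest.raises(ArgumentError):
            h.antialias_downsample(h.ECGSignal(np.zeros(100), fs=100.0))


class TestDetectQRS:
    def test_known_beats_recovered_within_10ms(self):
        truth = np.arange(1.0, 11.0)  # beats at 1..10 s
        ecg = h.generate_ecg(h.BeatTimeSeries(truth), fs=1000.0, noise_sd=0.0)
        beats = h.detect_qrs(h.antialias_downsample(ecg))
        assert len(beats) == truth.size
        assert np.max(np.abs(beats.beat_times - truth)) <= 0.010

    def test_all_zero_signal_raises(self):
        ecg = h.ECGSignal(np.zeros(4000), fs=200.0)
        with pytest.raises(NoQRSDetectedError):
            h.detect_qrs(ecg)

    def test_wrong_rate_and_short_record_rejected(self):
        with pytest.raises(ArgumentError):
            h.detect_qrs(h.ECGSignal(np.zeros(4000), fs=1000.0))
        with pytest.raises(ArgumentError):
            h.detect_qrs(h.ECGSignal(np.zeros(400), fs=200.0))

    def test_refractory_period_and_grid_quantization(self):
        truth = np.arange(1.0, 30.0, 0.7)
        ecg = h.generate_ecg(
            h.BeatTimeSeries(truth), fs=1000.0, noise_sd=0.05, seed=1
        )
        beats = h.detect_qrs(h.antialias_downsample(ecg))
        assert np.all(np.diff(beats.beat_times) >= 0.2 - 1e-12)
        # Beat timestamps live on the 200 Hz grid: 5 ms resolution.
        remainders = np.abs(beats.beat_times * 200.0 - np.round(beats.beat_times * 200.0))
        assert np.max(remainders) < 1e-9


class TestFlagOutlierIBIs:
    def test_zero_variance_record_is_clean(self):
        beats = h.BeatTimeSeries(np.arange(0.0, 10.0))
        flagged = h.flag_outlier_ibis(beats)
        assert np.all(flagged.flags == FLAG_OK)

    def test_single_long_ibi_flagged(self):
        # 49 IBIs of 1000 ms and one of 2000 ms: mean 1019.6 ms, SD 141.4 ms
        # (ddof=1), upper bound ~1302 ms, so only the 2000 ms beat is out.
        times = np.concatenate([np.arange(0.0, 50.0), [51.0]])
        beats = h.BeatTimeSeries(times)
        flagged = h.flag_outlier_ibis(beats)
        assert flagged.flags[-1] == FLAG_OUTLIER
        assert np.all(flagged.flags[:-1] == FLAG_OK)

    def test_idempotent(self):
        times = np.concatenate([np.arange(0.0, 50.0), [51.0]])
        once = h.flag_outlier_ibis(h.BeatTimeSeries(times))
        twice = h.flag_outlier_ibis(once)
        assert np.array_equal(once.flags, twice.flags)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ArgumentError):
            h.flag_outlier_ibis(h.BeatTimeSeries(np.array([0.0, 1.0])))


class TestCorrectBeats:
    @pytest.fixture()
    def flagged_series(self):
        times = np.array([0.0, 1.0, 1.1, 2.0, 3.0])
        flags = np.array([FLAG_OK, FLAG_OK, FLAG_OUTLIER, FLAG_OK, FLAG_OK])
        return h.BeatTimeSeries(times, flags=flags)

    def test_clean_series_unchanged_by_any_policy(self):
        beats = h.BeatTimeSeries(np.arange(0.0, 5.0))
        for policy in ("delete", "interpolate", "none"):
            out = h.correct_beats(beats, policy)
            assert np.array_equal(out.beat_times, beats.beat_times)

    def test_delete_removes_flagged_beat(self, flagged_series):
        out = h.correct_beats(flagged_series, "delete")
        assert np.allclose(out.beat_times, [0.0, 1.0, 2.0, 3.0])
        assert np.allclose(out.ibis[1:], 1000.0)

    def test_interpolate_equalizes_adjacent_ibis(self, flagged_series):
        out = h.correct_beats(flagged_series, "interpolate")
        assert np.allclose(out.beat_times, [0.0, 1.0, 1.5, 2.0, 3.0])
        assert out.flags[2] == FLAG_CORRECTED

    def test_unknown_policy_rejected(self, flagged_series):
        with pytest.raises(ConfigurationError):
            h.correct_beats(flagged_series, "bogus")

    def test_flag_delete_reflag_finds_nothing_new(self):
        # Regular rhythm with one spurious extra detection: the extra beat
        # splits an IBI into 0.1 + 0.9 s; only the 0.1 s IBI is an
        # outlier, deleting it restores the regular train exactly.
        times = np.arange(0.0, 61.0)
        times = np.sort(np.concatenate([times, [times[30] + 0.1]]))
        cleaned = h.correct_beats(
            h.flag_outlier_ibis(h.BeatTimeSeries(times)), "delete"
        )
        reflagged = h.flag_outlier_ibis(cleaned)
        assert np.all(reflagged.flags == FLAG_OK)
        assert np.allclose(reflagged.ibis[1:], 1000.0)


def test_detector_performance_on_long_noisy_record():
    """Sensitivity/PPV >= 99.5% and median timing error <= 5 ms at 75 bpm."""
    from conftest import match_beats

    hp = h.HeartPeriodSeries(np.full(3001, 800.0), fs=10.0)
    truth = h.generate_beats(hp, seed=5)
    ecg = h.generate_ecg(truth, fs=1000.0, noise_sd=0.1, seed=6,
                         duration=hp.duration)
    beats = h.detect_qrs(h.antialias_downsample(ecg))
    tp, fn, fp, errors = match_beats(truth.beat_times, beats.beat_times)
    assert tp / (tp + fn) >= 0.995
    assert tp / (tp + fp) >= 0.995
    assert np.median(errors) <= 0.005
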