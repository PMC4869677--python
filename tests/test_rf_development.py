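import numpy as np
import pytest

import hprglm as h
from hprglm.events import EventSchedule
from hprglm.exceptions import ArgumentError
from hprglm.rf_development import (
    EPOCH_WINDOW,
    elbow_n_keep,
    epoch_length,
    fit_gaussian_peaks,
)


def filtered_series(values, fs=10.0):
    return h.HeartPeriodSeries(np.asarray(values, float), fs=fs, filtered=True)


def schedule_at(onsets, session_length):
    onsets = np.asarray(onsets, dtype=float)
    return EventSchedule(
        onsets, np.full(onsets.shape, "a", dtype="<U32"), session_length
    )


class TestEpoching:
    def test_row_length_is_311_samples_at_10hz(self):
        assert epoch_length(10.0) == 311
        hp = filtered_series(np.random.default_rng(0).normal(0, 1, 1200))
        epochs = h.epoch_and_center(hp, schedule_at([20.0, 60.0], 90.0))
        assert epochs.data.shape == (2, 311)
        assert epochs.times[0] == EPOCH_WINDOW[0]
        assert epochs.times[-1] == pytest.approx(EPOCH_WINDOW[1])

    def test_constant_signal_centers_to_zero(self):
        hp = filtered_series(np.full(1000, 7.0))
        epochs = h.epoch_and_center(hp, schedule_at([20.0], 60.0))
        assert np.allclose(epochs.data, 0.0)

    def test_event_too_close_to_record_start_dropped(self):
        hp = filtered_series(np.zeros(700))
        epochs = h.epoch_and_center(hp, schedule_at([1.0, 30.0], 65.0))
        assert epochs.n_epochs == 1
        assert epochs.n_dropped == 1

    def test_no_retained_epochs_raises(self):
        hp = filtered_series(np.zeros(100))
        with pytest.raises(ArgumentError):
            h.epoch_and_center(hp, schedule_at([1.0], 40.0))

    def test_unfiltered_input_rejected(self):
        hp = h.HeartPeriodSeries(np.full(1000, 800.0), fs=10.0)
        with pytest.raises(ArgumentError):
            h.epoch_and_center(hp, schedule_at([20.0], 60.0))


class TestPCA:
    @staticmethod
    def planted_epochs(waveforms, scales, seed=0):
        rng = np.random.default_rng(seed)
        n = epoch_length(10.0)
        rows = []
        for _ in range(200):
            row = np.zeros(n)
            for w, s in zip(waveforms, scales):
                row += rng.normal(0, s) * w
            rows.append(row - row.mean())
        data = np.vstack(rows)
        return h.EpochMatrix(
            data=data,
            participants=np.array([f"p{i % 10}" for i in range(200)], dtype="<U32"),
            experiments=np.full(200, "e1", dtype="<U32"),
            conditions=np.full(200, "a", dtype="<U32"),
            fs=10.0,
        )

    @staticmethod
    def centered_waveform(center, width):
        t = EPOCH_WINDOW[0] + np.arange(epoch_length(10.0)) / 10.0
        w = np.exp(-((t - center) ** 2) / (2 * width**2))
        w -= w.mean()
        return w / np.linalg.norm(w)

    def test_rank_one_data_gives_single_dominant_component(self):
        epochs = self.planted_epochs([self.centered_waveform(5.0, 2.0)], [1.0])
        result = h.pca_epochs(epochs, n_keep=1)
        assert result.explained_fraction[0] > 0.999

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (40, epoch_length(10.0)))
        data -= data.mean(axis=1, keepdims=True)
        epochs = h.EpochMatrix(
            data=data,
            participants=np.full(40, "p0", dtype="<U32"),
            experiments=np.full(40, "e1", dtype="<U32"),
            conditions=np.full(40, "a", dtype="<U32"),
            fs=10.0,
        )
        result = h.pca_epochs(epochs, n_keep=3)
        assert result.explained_fraction_all.sum() == pytest.approx(1.0, abs=1e-10)

    def test_planted_variance_ratio_recovered(self):
        w1 = self.centered_waveform(4.0, 1.5)
        w2 = self.centered_waveform(20.0, 1.5)
        w2 -= (w2 @ w1) * w1  # enforce orthogonality after centering
        w2 /= np.linalg.norm(w2)
        epochs = self.planted_epochs([w1, w2], [2.0, 1.0], seed=5)
        result = h.pca_epochs(epochs, n_keep=2)
        ratio = result.explained_fraction[0] / result.explained_fraction[1]
        assert abs(ratio - 4.0) / 4.0 < 0.10

    def test_n_keep_beyond_rank_rejected(self):
        epochs = self.planted_epochs([self.centered_waveform(5.0, 2.0)], [1.0])
        with pytest.raises(ArgumentError):
            h.pca_epochs(epochs, n_keep=5)

    def test_elbow_rule_caps_at_default(self):
        frac = np.array([0.5, 0.3, 0.1, 0.05, 0.05])
        assert 1 <= elbow_n_keep(frac) <= 3


class TestGaussianPeakFitting:
    times = EPOCH_WINDOW[0] + np.arange(epoch_length(10.0)) / 10.0

    def test_single_gaussian_recovered_within_one_percent(self):
        w = 10.0 * np.exp(-((self.times - 3.0) ** 2) / (2 * 1.0**2))
        (comp,) = fit_gaussian_peaks(w, self.times)
        assert comp.amplitude == pytest.approx(10.0, rel=0.01)
        assert comp.center == pytest.approx(3.0, rel=0.01)
        assert comp.width == pytest.approx(1.0, rel=0.01)

    def test_flat_waveform_yields_no_components(self):
        assert fit_gaussian_peaks(np.zeros_like(self.times), self.times) == []

    def test_two_separated_peaks_recovered(self):
        w = 8.0 * np.exp(-((self.times - 4.0) ** 2) / (2 * 1.2**2)) - 6.0 * np.exp(
            -((self.times - 15.0) ** 2) / (2 * 1.5**2)
        )
        comps = fit_gaussian_peaks(w, self.times)
        assert len(comps) == 2
        assert comps[0].center == pytest.approx(4.0, abs=0.2)
        assert comps[1].center == pytest.approx(15.0, abs=0.2)
        assert comps[0].amplitude > 0 > comps[1].amplitude


class TestQualification:
    def test_uniform_positive_response_is_stable(self):
        rng = np.random.default_rng(0)
        estimates = {
            e: 10.0 + rng.normal(0, 0.1, 20) for e in ("e1", "e2", "e3")
        }
        result = h.qualify_rf(estimates)
        assert result.stable_direction and result.direction == "+"
        assert result.retained

    def test_condition_separation_detected_with_high_power(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            estimates = {
                "e1": rng.normal(0, 1, 40),
                "e2": rng.normal(0, 1, 40),
                "e3": rng.normal(3, 1, 40),
            }
            hits += h.qualify_rf(estimates).separates_conditions
        assert hits == 20  # power > 0.99 at this separation

    def test_null_retention_rate_near_alpha(self):
        retained = 0
        n_sims = 60
        for seed in range(n_sims):
            rng = np.random.default_rng(1000 + seed)
            estimates = {e: rng.normal(0, 1, 40) for e in ("e1", "e2", "e3")}
            retained += h.qualify_rf(estimates).retained
        assert retained / n_sims <= 0.15

    def test_small_groups_rejected(self):
        with pytest.raises(ArgumentError):
            h.qualify_rf({"e1": np.array([1.0]), "e2": np.array([1.0, 2.0])})


class TestStepwiseSelection:
    def test_single_planted_candidate_retained_via_stable_direction(self):
        data = h.generate_development_study(1, n_participants=4, n_events=8)
        candidates, _ = h.development_candidates()
        result = h.stepwise_select([candidates[0]], data)
        assert result.selected_labels == ("cand1",)
        assert result.basis.orthogonalized

    def test_planted_pair_recovered_and_spurious_rejected(self):
        data = h.generate_development_study(2)
        candidates, true_idx = h.development_candidates()
        result = h.stepwise_select(candidates, data)
        assert result.selected_labels == tuple(
            candidates[i].label for i in true_idx
        )
        steps = {entry["rf"] for entry in result.log if entry.get("step") == 1}
        assert steps == {rf.label for rf in candidates}

    def test_requires_two_experiments(self):
        data = h.generate_development_study(3, n_participants=2, n_events=4)
        candidates, _ = h.development_candidates()
        with pytest.raises(ArgumentError):
            h.stepwise_select(candidates, {"exp1": data["exp1"]})
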