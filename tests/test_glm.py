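import numpy as np
import pytest

import hprglm as h
from hprglm.events import EventSchedule
from hprglm.exceptions import ArgumentError, EstimationError
from hprglm.glm import DesignMatrix

from conftest import simulate_session


def schedule_at(onsets, session_length, conditions=None):
    onsets = np.asarray(onsets, dtype=float)
    if conditions is None:
        conditions = np.full(onsets.shape, "a", dtype="<U32")
    return EventSchedule(
        onsets, np.asarray(conditions, dtype="<U32"), session_length
    )


def single_rf_basis(amplitude=20.0, center=3.0, width=1.5):
    rf = h.ResponseFunction(
        h.GaussianComponent(amplitude, center, width), fs=10.0, label="RF1"
    )
    return h.BasisSet((rf,), fs=10.0)


class TestDesignMatrix:
    def test_single_event_regressor_is_shifted_rf_shape(self):
        basis = single_rf_basis()
        sched = schedule_at([20.0], 60.0)
        design = h.build_design_matrix(
            sched, basis, n_samples=600, fs=10.0, filtered_like_data=False
        )
        reg = design.X[:, 0]
        shape = basis.shapes[0]
        i0 = round(20.0 * 10) - 50  # onset shifted by the 5 s prestimulus
        assert np.allclose(reg[i0 : i0 + shape.size], shape)
        assert np.allclose(np.delete(reg, np.arange(i0, i0 + shape.size)), 0.0)

    def test_two_distant_events_superpose_additively(self):
        basis = single_rf_basis()
        both = h.build_design_matrix(
            schedule_at([20.0, 70.0], 120.0), basis, 1200, 10.0,
            filtered_like_data=False,
        )
        one = h.build_design_matrix(
            schedule_at([20.0], 120.0), basis, 1200, 10.0,
            filtered_like_data=False,
        )
        two = h.build_design_matrix(
            schedule_at([70.0], 120.0), basis, 1200, 10.0,
            filtered_like_data=False,
        )
        assert np.allclose(both.X[:, 0], one.X[:, 0] + two.X[:, 0], atol=1e-15)

    def test_regressor_equals_brute_force_shifted_sum(self, canonical):
        # Independent oracle: loop over events and samples, evaluating each
        # Gaussian directly on the time grid.
        onsets = [12.0, 47.3, 81.9]
        fs, n = 10.0, 1200
        sched = schedule_at(onsets, 119.0)
        design = h.build_design_matrix(
            sched, canonical, n, fs, filtered_like_data=False
        )
        t = np.arange(n) / fs
        for j, rf in enumerate(canonical.rfs):
            brute = np.zeros(n)
            for onset in onsets:
                snapped = round(onset * fs) / fs
                tt = t - snapped
                inside = (tt >= -5.0 - 1e-12) & (tt <= 30.0 + 1e-12)
                gauss = np.exp(-((tt - rf.center) ** 2) / (2 * rf.width**2))
                brute += np.where(inside, np.sign(rf.amplitude) * gauss, 0.0)
            assert np.max(np.abs(design.X[:, j] - brute)) < 1e-12

    def test_empty_schedule_rejected(self, canonical):
        empty = EventSchedule(
            np.empty(0), np.empty(0, dtype="<U32"), session_length=10.0
        )
        with pytest.raises(ArgumentError):
            h.build_design_matrix(empty, canonical, 600, 10.0)

    def test_overlap_warning_for_short_itis(self, canonical):
        sched = h.generate_schedule("exp4", 10, seed=1)
        n = int(sched.session_length * 10)
        with pytest.warns(h.OverlapWarning):
            h.build_design_matrix(sched, canonical, n, 10.0)

    def test_no_overlap_warning_for_long_itis(self, canonical, recwarn):
        sched = h.generate_schedule("exp1", 5, seed=1)
        n = int(sched.session_length * 10)
        h.build_design_matrix(sched, canonical, n, 10.0)
        assert not any(
            isinstance(w.message, h.OverlapWarning) for w in recwarn.list
        )


class TestFitGLM:
    def test_noiseless_recovery_is_exact(self, canonical):
        sched = h.generate_schedule("exp3", 15, seed=3)
        amps = {
            c: tuple(10.0 + 3.0 * i + j for j in range(6))
            for i, c in enumerate(sched.condition_set)
        }
        hp = simulate_session(sched, canonical, amps, seed=4)
        hpf = h.bandpass_heart_period(hp)
        design = h.build_design_matrix(sched, canonical, len(hpf), 10.0)
        fit = h.fit_glm(hpf, design)
        for c in sched.condition_set:
            assert np.allclose(
                fit.condition_amplitudes(c), amps[c], atol=1e-8
            )

    def test_residuals_orthogonal_to_design(self, canonical):
        sched = h.generate_schedule("exp1", 10, seed=5)
        amps = {"noise": tuple(15.0 for _ in range(6))}
        hp = simulate_session(sched, canonical, amps, seed=6, noise_sd=5.0)
        hpf = h.bandpass_heart_period(hp)
        design = h.build_design_matrix(sched, canonical, len(hpf), 10.0)
        fit = h.fit_glm(hpf, design)
        for j in range(design.X.shape[1]):
            col = design.X[:, j]
            bound = 1e-6 * np.linalg.norm(col) * np.linalg.norm(fit.residuals)
            assert abs(col @ fit.residuals) < max(bound, 1e-9)

    def test_fitted_plus_residuals_reconstruct_data(self, canonical):
        sched = h.generate_schedule("exp1", 8, seed=8)
        amps = {"noise": tuple(15.0 for _ in range(6))}
        hp = simulate_session(sched, canonical, amps, seed=9, noise_sd=5.0)
        hpf = h.bandpass_heart_period(hp)
        design = h.build_design_matrix(sched, canonical, len(hpf), 10.0)
        fit = h.fit_glm(hpf, design)
        assert np.allclose(fit.fitted.values + fit.residuals, hpf.values)

    def test_rank_deficient_design_names_dependent_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        X = np.column_stack([x, 2.0 * x, np.ones(200)])
        design = DesignMatrix(
            X=X,
            labels=("a:RF1", "a:RF2", "intercept"),
            conditions=("a",),
            n_rfs=2,
            fs=10.0,
            filtered_like_data=False,
            condition_n={"a": 1},
        )
        hp = h.HeartPeriodSeries(rng.normal(0, 1, 200), fs=10.0, filtered=True)
        with pytest.raises(EstimationError, match="RF"):
            h.fit_glm(hp, design)

    def test_unfiltered_data_rejected(self, canonical):
        sched = h.generate_schedule("exp1", 5, seed=1)
        amps = {"noise": tuple(15.0 for _ in range(6))}
        hp = simulate_session(sched, canonical, amps)
        design = h.build_design_matrix(sched, canonical, len(hp), 10.0)
        with pytest.raises(ArgumentError):
            h.fit_glm(hp, design)

    def test_orthogonalized_basis_spans_same_fitted_values(self, canonical):
        sched = h.generate_schedule("exp1", 10, seed=12)
        amps = {"noise": tuple(12.0 + j for j in range(6))}
        hp = simulate_session(sched, canonical, amps, seed=13, noise_sd=5.0)
        hpf = h.bandpass_heart_period(hp)
        raw_fit = h.fit_glm(
            hpf, h.build_design_matrix(sched, canonical, len(hpf), 10.0)
        )
        ortho = h.gram_schmidt_basis(canonical)
        ortho_fit = h.fit_glm(
            hpf, h.build_design_matrix(sched, ortho, len(hpf), 10.0)
        )
        assert np.allclose(
            raw_fit.fitted.values, ortho_fit.fitted.values, atol=1e-8
        )

    def test_mean_recovery_under_noise(self, canonical):
        # Monte-Carlo: white noise 5 ms, mean estimate within 5% per
        # coefficient (reduced-seed version of the headline property).
        truth = np.array([30.0, 25.0, 20.0, 15.0, 12.0, 10.0])
        errors = []
        for seed in range(10):
            sched = h.generate_schedule("exp1", 20, seed=seed)
            amps = {"noise": tuple(truth)}
            hp = simulate_session(
                sched, canonical, amps, seed=100 + seed, noise_sd=5.0
            )
            hpf = h.bandpass_heart_period(hp)
            design = h.build_design_matrix(sched, canonical, len(hpf), 10.0)
            fit = h.fit_glm(hpf, design)
            errors.append(fit.condition_amplitudes("noise") - truth)
        mean_err = np.abs(np.mean(errors, axis=0))
        assert np.all(mean_err / truth < 0.05)
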