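import numpy as np
import pytest

import hprglm as h


@pytest.fixture(scope="session")
def canonical():
    return h.canonical_basis()


@pytest.fixture()
def long_iti_schedule():
    return h.generate_schedule("exp1", 20, seed=7)


def simulate_session(
    schedule,
    basis,
    amplitudes,
    seed=0,
    noise_sd=0.0,
    rsa_amplitude=0.0,
    drift_amplitude=0.0,
    fs=10.0,
):
    """Noise-configurable forward simulation used across test modules."""
    truth = h.SimulationGroundTruth(
        true_amplitudes=amplitudes,
        noise_sd=noise_sd,
        rsa_amplitude=rsa_amplitude,
        drift_amplitude=drift_amplitude,
        seed=seed,
    )
    return h.generate_heart_period(schedule, basis, truth, fs=fs)


@pytest.fixture()
def simulate():
    return simulate_session


def match_beats(true_times, detected_times, tol_s=0.05):
    """Greedy one-to-one matching; returns (tp, fn, fp, abs errors in s)."""
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    used = np.zeros(detected_times.size, dtype=bool)
    errors = []
    for t in true_times:
        if detected_times.size == 0:
            break
        free = np.flatnonzero(~used)
        if free.size == 0:
            break
        i = free[np.argmin(np.abs(detected_times[free] - t))]
        if abs(detected_times[i] - t) <= tol_s:
            used[i] = True
            errors.append(abs(detected_times[i] - t))
    tp = len(errors)
    return tp, true_times.size - tp, detected_times.size - tp, np.array(errors)
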