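"""Forward simulation: ground-truth heart period, beat trains, and ECG.

The simulator implements the same linear time-invariant (LTI) forward model
the analysis inverts: an event elicits, per response function (RF), a
deflection of the heart period equal to a planted amplitude (ms) times the
RF's unit-peak shape.  On top of the event-related signal it adds the
dominant nuisance processes of real heart-period data in minimal form —
respiratory sinus arrhythmia (RSA) as a single sinusoid, slow drift as a
very-low-frequency sinusoid, and white measurement noise.

Beats are generated from the heart-period signal by integral pulse
frequency modulation (IPFM): a beat is emitted whenever the running
integral of the instantaneous rate (1000 / heart period) crosses successive
integers.  ECG is rendered by placing a fixed synthetic P-QRS-T template
(dominant R spike) at each beat time.

Event onsets are snapped to the heart-period sample grid when the
event-related signal is rendered, matching the onset rasterization of the
GLM design matrix, so that noiseless simulations are exactly representable
by the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet
from .events import EventSchedule
from .exceptions import ArgumentError, DomainError
from .series import BeatTimeSeries, ECGSignal, HeartPeriodSeries

__all__ = [
    "SimulationGroundTruth",
    "generate_heart_period",
    "generate_beats",
    "generate_ecg",
    "development_candidates",
    "generate_development_study",
]


@dataclass(frozen=True)
class SimulationGroundTruth:
    """Planted parameters of one simulated recording.

    ``true_amplitudes`` maps each condition label to one amplitude (ms) per
    RF of the simulation basis; amplitudes scale the RF's unit-peak signed
    shape, so a positive amplitude on a deceleratory (positive) RF lengthens
    the heart period by that many milliseconds at the RF's peak.
    """

    true_amplitudes: dict[str, tuple[float, ...]]
    mean_heart_period: float = 850.0  # ms, ~70 bpm
    rsa_amplitude: float = 30.0  # ms
    rsa_frequency: float = 0.25  # Hz, typical adult breathing rate
    drift_amplitude: float = 50.0  # ms
    drift_frequency: float = 0.005  # Hz, below the 0.01 Hz high-pass corner
    noise_sd: float = 5.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if not 600.0 <= self.mean_heart_period <= 1200.0:
            raise ArgumentError(
                "mean heart period must lie in [600, 1200] ms, got "
                f"{self.mean_heart_period}"
            )
        if self.noise_sd < 0:
            raise ArgumentError("noise SD must be non-negative")
        if not 0.1 < self.rsa_frequency < 0.5:
            raise ArgumentError("RSA frequency must lie in (0.1, 0.5) Hz")


def generate_heart_period(
    schedule: EventSchedule,
    basis: BasisSet,
    truth: SimulationGroundTruth,
    fs: float = 10.0,
) -> HeartPeriodSeries:
    """Render the ground-truth heart-period signal of one session.

    signal = mean heart period
           + sum over events of amplitude(condition, RF) x RF unit shape
           + RSA sinusoid + slow drift + white noise.

    RSA and drift phases and the noise stream are drawn from
    ``truth.seed``; set the respective amplitudes (or ``noise_sd``) to zero
    for a noiseless variant.
    """
    if fs <= 0:
        raise ArgumentError("fs must be positive")
    if len(basis) == 0:
        raise ArgumentError("basis must be non-empty")
    for condition in schedule.condition_set:
        amps = truth.true_amplitudes.get(condition)
        if amps is None or len(amps) != len(basis):
            raise ArgumentError(
                f"true_amplitudes must give one value per RF for {condition!r}"
            )

    n = int(round(schedule.session_length * fs))
    t = np.arange(n) / fs
    values = np.full(n, truth.mean_heart_period)

    # Place the same sampled unit-peak shapes the design matrix uses, so a
    # noiseless simulation is exactly representable by the GLM.
    offset = round(5.0 * fs)  # prestimulus support
    unit_shapes = [rf.unit_shape() for rf in basis.rfs]
    for onset, condition in zip(schedule.onsets, schedule.conditions):
        i0 = round(onset * fs) - offset
        amps = truth.true_amplitudes[condition]
        for amp, shape in zip(amps, unit_shapes):
            lo, hi = max(0, i0), min(n, i0 + shape.size)
            values[lo:hi] += amp * shape[lo - i0 : hi - i0]

    rng = np.random.default_rng(truth.seed)
    rsa_phase, drift_phase = rng.uniform(0, 2 * np.pi, size=2)
    values += truth.rsa_amplitude * np.sin(
        2 * np.pi * truth.rsa_frequency * t + rsa_phase
    )
    values += truth.drift_amplitude * np.sin(
        2 * np.pi * truth.drift_frequency * t + drift_phase
    )
    if truth.noise_sd > 0:
        values += rng.normal(0.0, truth.noise_sd, size=n)
    return HeartPeriodSeries(values, fs=fs, start_time=0.0, filtered=False)


def generate_beats(hp: HeartPeriodSeries, seed: int) -> BeatTimeSeries:
    """Emit a beat train from a heart-period signal by IPFM.

    The instantaneous rate ``1000 / hp(t)`` (beats/s) is integrated with the
    trapezoid rule on the signal's grid; a beat occurs wherever the integral
    crosses successive integers.  ``seed`` sets the (uniform) initial phase
    of the integrator, i.e. where in the cycle the record starts.
    """
    values = hp.values
    if values.size < 2:
        raise ArgumentError("heart-period series too short to generate beats")
    if values.min() <= 0:
        raise DomainError("heart period must be strictly positive everywhere")
    rate = 1000.0 / values  # beats per second
    t = hp.times
    integral = np.concatenate(
        [[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0) / hp.fs]
    )
    phase0 = np.random.default_rng(seed).uniform(0.0, 1.0)
    levels = np.arange(phase0, integral[-1], 1.0)
    if levels.size < 1:
        raise ArgumentError("record too short: no beat emitted")
    beat_times = np.interp(levels, integral, t)
    return BeatTimeSeries(beat_times)


# P-QRS-T template: (amplitude, centre s relative to R peak, sigma s).
# Only the R spike's prominence matters for detection; P and T give the
# trace a recognizable morphology.
_ECG_TEMPLATE = (
    (0.12, -0.16, 0.020),  # P
    (-0.15, -0.026, 0.008),  # Q
    (1.00, 0.0, 0.011),  # R
    (-0.20, 0.026, 0.009),  # S
    (0.30, 0.22, 0.045),  # T
)
#: Temporal extent of the template around the R peak, seconds.
_TEMPLATE_SPAN = (-0.24, 0.36)


def generate_ecg(
    beats: BeatTimeSeries,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float | None = None,
) -> ECGSignal:
    """Render synthetic ECG by placing the P-QRS-T template at each beat.

    The template is evaluated continuously, so the R-peak of each placed
    template coincides with the beat time to within half a sample at any
    rate.  Additive Gaussian noise with SD ``noise_sd`` (in units of the R
    amplitude, which is 1) is drawn from ``seed``.
    """
    if fs < 250.0:
        raise ArgumentError(f"fs must be >= 250 Hz for template fidelity, got {fs}")
    times = beats.beat_times
    span = _TEMPLATE_SPAN[1] - _TEMPLATE_SPAN[0]
    if times.size >= 2 and np.min(np.diff(times)) < span:
        raise DomainError(
            f"interbeat interval shorter than the {span:.2f} s ECG template"
        )
    if duration is None:
        duration = (times[-1] + 1.0) if times.size else 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    samples = np.zeros(n)
    for b in times:
        sl = slice(
            max(0, int(np.ceil((b + _TEMPLATE_SPAN[0]) * fs))),
            min(n, int(np.floor((b + _TEMPLATE_SPAN[1]) * fs)) + 1),
        )
        tt = t[sl] - b
        for amp, center, width in _ECG_TEMPLATE:
            samples[sl] += amp * np.exp(-((tt - center) ** 2) / (2.0 * width**2))
    if noise_sd > 0:
        samples += np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return ECGSignal(samples, fs=fs)


# ---------------------------------------------------------------------------
# Packaged development study: planted basis recovery
# ---------------------------------------------------------------------------

#: Per-experiment planted amplitudes (ms) for the two true development RFs.
_DEV_AMPLITUDES = {
    "exp1": (40.0, 50.0),
    "exp2_oddball": (40.0, 20.0),
    "exp3": (70.0, 50.0),
}
_DEV_BETWEEN_SUBJECT_SD = 10.0  # ms
_DEV_TRUE_PARAMS = ((30.0, 2.0, 1.2), (-25.0, 7.0, 1.5))
_DEV_SPURIOUS_PARAMS = ((15.0, 16.0, 1.5), (-15.0, 22.0, 1.5))


def development_candidates(fs: float = 10.0):
    """Candidate RFs for the packaged basis-development study.

    Returns ``(candidates, true_indices)``: four Gaussian RFs in ascending
    centre order, of which the first two carry planted event-related signal
    (an early deceleration and a mid-latency acceleration) and the last two
    are spurious late components with zero planted amplitude.
    """
    from .basis import GaussianComponent, ResponseFunction

    params = _DEV_TRUE_PARAMS + _DEV_SPURIOUS_PARAMS
    candidates = [
        ResponseFunction(GaussianComponent(a, c, w), fs=fs, label=f"cand{i + 1}")
        for i, (a, c, w) in enumerate(params)
    ]
    return candidates, (0, 1)


def generate_development_study(
    seed: int,
    n_participants: int = 10,
    n_events: int = 15,
    fs: float = 10.0,
):
    """Simulate the three-experiment basis-development dataset.

    Each of the three long-ITI experiments contributes ``n_participants``
    simulated participants; per participant the two true development RFs are
    planted with experiment-specific amplitudes plus between-participant
    jitter (SD 10 ms), on top of RSA, drift, and 5 ms white noise.  Records
    are band-pass filtered, ready for epoching or GLM fitting.

    Returns
    -------
    dict mapping experiment name to a list of
    :class:`~hprglm.rf_development.ParticipantRecord`.
    """
    from .basis import BasisSet as _BasisSet
    from .events import generate_schedule
    from .heart_period import bandpass_heart_period
    from .rf_development import ParticipantRecord

    candidates, true_idx = development_candidates(fs)
    true_basis = _BasisSet(
        tuple(candidates[i] for i in true_idx), fs=fs, provenance="development-truth"
    )
    rng = np.random.default_rng(seed)
    datasets: dict[str, list[ParticipantRecord]] = {}
    for exp, base_amps in _DEV_AMPLITUDES.items():
        records = []
        for p in range(n_participants):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            schedule = generate_schedule(exp, n_events, seed=sub_seed)
            amps = tuple(
                float(a + rng.normal(0.0, _DEV_BETWEEN_SUBJECT_SD))
                for a in base_amps
            )
            truth = SimulationGroundTruth(
                true_amplitudes={c: amps for c in schedule.condition_set},
                mean_heart_period=float(rng.uniform(700.0, 1000.0)),
                seed=sub_seed,
            )
            hp = generate_heart_period(schedule, true_basis, truth, fs=fs)
            records.append(
                ParticipantRecord(
                    participant=f"{exp}-p{p:02d}",
                    hp=bandpass_heart_period(hp),
                    schedule=schedule,
                    experiment=exp,
                )
            )
        datasets[exp] = records
    return datasets
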