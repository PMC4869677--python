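"""ECG preprocessing: antialias downsampling, offline QRS detection, and
statistical interbeat-interval correction.

The detector is an offline adaptation of the Pan-Tompkins real-time QRS
algorithm.  The classic chain — band-pass (5-15 Hz), differentiate, square,
moving-window integrate (150 ms), adaptive dual thresholds with search-back
for missed beats — is kept, with three offline modifications: all filters
are zero-phase (forward-backward), the record is processed twice with the
second pass initialized from the thresholds learned in the first, and beat
times are refined to the R-peak of the raw trace.  Beat times land on the
200 Hz working grid, i.e. with 5 ms resolution.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .exceptions import ArgumentError, ConfigurationError, NoQRSDetectedError
from .series import (
    FLAG_CORRECTED,
    FLAG_OK,
    FLAG_OUTLIER,
    BeatTimeSeries,
    ECGSignal,
)

#: Working sampling rate of the detector, Hz.
WORKING_FS = 200.0
#: Refractory period between detected beats, seconds.
REFRACTORY_S = 0.2
#: Search-back window for missed beats, seconds.
SEARCHBACK_S = 0.36
#: Moving-window-integration length, seconds.
MWI_S = 0.15


def antialias_downsample(ecg: ECGSignal) -> ECGSignal:
    """Low-pass filter and resample raw ECG to the 200 Hz working rate.

    A second-order Butterworth low-pass at 100 Hz is applied zero-phase
    before decimation; integer rate ratios are decimated by slicing,
    non-integer ratios are linearly resampled onto the 200 Hz grid.
    """
    if ecg.fs < WORKING_FS:
        raise ArgumentError(
            f"input rate {ecg.fs} Hz is below the {WORKING_FS} Hz working rate"
        )
    if ecg.fs == WORKING_FS:
        return ECGSignal(ecg.samples.copy(), fs=WORKING_FS)
    sos = sps.butter(2, 100.0, btype="low", fs=ecg.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, ecg.samples)
    ratio = ecg.fs / WORKING_FS
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:: int(round(ratio))]
    else:
        n_out = int(round(ecg.samples.size / ratio))
        out = np.interp(
            np.arange(n_out) / WORKING_FS, ecg.times, filtered
        )
    return ECGSignal(out, fs=WORKING_FS)


def _feature_signal(samples: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Pan-Tompkins feature chain: band-passed trace and integrated energy."""
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, samples)
    deriv = np.gradient(band) * fs
    squared = deriv**2
    win = max(1, int(round(MWI_S * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    return band, mwi


def _threshold_pass(
    peaks: np.ndarray,
    mwi: np.ndarray,
    fs: float,
    spk_init: float,
    npk_init: float,
) -> tuple[list[int], float, float]:
    """One adaptive-threshold pass over candidate MWI peaks.

    Implements the running signal/noise peak estimates (SPK/NPK), the
    detection threshold NPK + 0.25 (SPK - NPK), and search-back: if more
    than 1.66 times the running average beat interval has elapsed, the
    largest skipped candidate above half the threshold is accepted.
    """
    spk, npk = spk_init, npk_init
    qrs: list[int] = []
    rr_history: list[float] = []
    skipped: list[int] = []
    for idx in peaks:
        thresh = npk + 0.25 * (spk - npk)
        if mwi[idx] > thresh:
            accept = True
        else:
            accept = False
            # Search-back for a missed beat.
            if qrs and rr_history:
                avg_rr = float(np.mean(rr_history[-8:]))
                if (idx - qrs[-1]) / fs > 1.66 * avg_rr:
                    window = [
                        j
                        for j in skipped
                        if j > qrs[-1] and mwi[j] > 0.5 * thresh
                    ]
                    if window:
                        back = max(window, key=lambda j: mwi[j])
                        if (back - qrs[-1]) / fs >= REFRACTORY_S:
                            qrs.append(back)
                            rr_history.append((qrs[-1] - qrs[-2]) / fs)
                            spk = 0.25 * mwi[back] + 0.75 * spk
                        skipped = []
        if accept:
            if qrs and (idx - qrs[-1]) / fs < REFRACTORY_S:
                # Within the refractory window: keep the larger peak.
                if mwi[idx] > mwi[qrs[-1]]:
                    qrs[-1] = idx
                continue
            if qrs:
                rr_history.append((idx - qrs[-1]) / fs)
            qrs.append(idx)
            spk = 0.125 * mwi[idx] + 0.875 * spk
            skipped = []
        else:
            npk = 0.125 * mwi[idx] + 0.875 * npk
            skipped.append(idx)
    return qrs, spk, npk


def detect_qrs(ecg: ECGSignal) -> BeatTimeSeries:
    """Detect QRS complexes in a 200 Hz ECG record.

    Apply :func:`antialias_downsample` first; records shorter than 10 s are
    rejected because the adaptive thresholds need a learning stretch.

    Raises
    ------
    NoQRSDetectedError
        If no beat exceeds the adaptive thresholds anywhere in the record.
    """
    if ecg.fs != WORKING_FS:
        raise ArgumentError(
            f"detector expects {WORKING_FS} Hz input, got {ecg.fs} Hz; "
            "run antialias_downsample first"
        )
    if ecg.duration < 10.0:
        raise ArgumentError("record must be at least 10 s long")
    fs = ecg.fs
    _, mwi = _feature_signal(ecg.samples, fs)
    min_dist = int(round(REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(mwi, distance=min_dist)
    if peaks.size == 0 or mwi.max() <= 0:
        raise NoQRSDetectedError("no QRS detected: featureless record")

    # Threshold initialization from the first two seconds, as in the
    # original algorithm; pass 2 is re-initialized from pass-1 estimates.
    learn = mwi[: int(2 * fs)]
    spk0 = 0.875 * float(learn.max())
    npk0 = 0.5 * float(learn.mean())
    qrs1, spk, npk = _threshold_pass(peaks, mwi, fs, spk0, npk0)
    if not qrs1:
        raise NoQRSDetectedError("no QRS detected: no peak above threshold")
    qrs2, _, _ = _threshold_pass(peaks, mwi, fs, spk, npk)
    qrs = qrs2 if qrs2 else qrs1

    # Refine each detection to the R-peak of the raw trace and enforce the
    # refractory period on the refined times.
    half = int(round(0.075 * fs))
    refined: list[int] = []
    for idx in qrs:
        lo, hi = max(0, idx - half), min(ecg.samples.size, idx + half + 1)
        r = lo + int(np.argmax(ecg.samples[lo:hi]))
        if refined and (r - refined[-1]) / fs < REFRACTORY_S:
            if ecg.samples[r] > ecg.samples[refined[-1]]:
                refined[-1] = r
            continue
        refined.append(r)
    beat_times = np.asarray(refined, dtype=float) / fs
    return BeatTimeSeries(beat_times)


def flag_outlier_ibis(beats: BeatTimeSeries) -> BeatTimeSeries:
    """Flag beats whose IBI falls outside mean(IBI) +/- 2 SD of the record.

    Mean and SD (ddof=1) are computed once over all defined IBIs of the
    record.  With zero IBI variance no beat is flagged (the bounds collapse
    onto the mean and the comparison is strict).  Re-running on an already
    flagged series reproduces the same flags; beats previously marked
    ``corrected`` keep that mark unless their IBI is now an outlier.
    """
    if len(beats) < 3:
        raise ArgumentError("need at least 3 beats to estimate IBI statistics")
    ibis = beats.ibis
    defined = ibis[1:]
    mean, sd = float(np.mean(defined)), float(np.std(defined, ddof=1))
    outlier = np.zeros(len(beats), dtype=bool)
    outlier[1:] = np.abs(defined - mean) > 2.0 * sd
    flags = np.where(
        outlier,
        FLAG_OUTLIER,
        np.where(beats.flags == FLAG_CORRECTED, FLAG_CORRECTED, FLAG_OK),
    )
    return beats.with_flags(flags)


def correct_beats(beats: BeatTimeSeries, policy: str) -> BeatTimeSeries:
    """Apply a correction policy to beats flagged as outliers.

    ``delete``
        Remove flagged beats; IBIs are recomputed across the gap.
    ``interpolate``
        Move each flagged beat to the midpoint of its neighbours, which
        equalizes its two adjacent IBIs; moved beats are flagged
        ``corrected``.  A flagged first or last beat has only one
        neighbour and is deleted instead.
    ``none``
        Pass-through.
    """
    if policy not in ("delete", "interpolate", "none"):
        raise ConfigurationError(
            f"unknown correction policy {policy!r}; "
            "choose delete, interpolate, or none"
        )
    if policy == "none" or not np.any(beats.flags == FLAG_OUTLIER):
        return beats
    times = beats.beat_times.copy()
    flags = beats.flags.copy()
    if policy == "delete":
        keep = flags != FLAG_OUTLIER
        return BeatTimeSeries(times[keep], flags=flags[keep])
    # interpolate
    keep = np.ones(times.size, dtype=bool)
    for i in np.flatnonzero(flags == FLAG_OUTLIER):
        if i == 0 or i == times.size - 1:
            keep[i] = False
            continue
        times[i] = 0.5 * (times[i - 1] + times[i + 1])
        flags[i] = FLAG_CORRECTED
    return BeatTimeSeries(times[keep], flags=flags[keep])
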