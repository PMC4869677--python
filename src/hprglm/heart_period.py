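"""Beat series to evenly sampled heart period, and the model's band-pass.

Each interbeat interval is assigned to its following heartbeat; the points
(beat time, IBI) are linearly interpolated and sampled on a uniform grid
(canonically 10 Hz) anchored at t = 0 of the recording so that samples and
event onsets share one clock.  Outside [second beat, last beat] the series
is held at the nearest defined value: constant padding avoids spurious
ramps entering the subsequent filter.

The band-pass (second-order Butterworth, 0.01-2 Hz, applied zero-phase)
removes slow drift, smooths interpolation angles, and attenuates the
influence of remaining beat misdetections.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .exceptions import ArgumentError
from .series import BeatTimeSeries, HeartPeriodSeries

#: Canonical heart-period sampling rate, Hz.
HP_FS = 10.0
#: Band-pass corner frequencies, Hz.
BANDPASS = (0.01, 2.0)


def beats_to_heart_period(
    beats: BeatTimeSeries,
    fs: float = HP_FS,
    duration: float | None = None,
) -> HeartPeriodSeries:
    """Interpolate a beat train to an evenly sampled heart-period series.

    Parameters
    ----------
    beats:
        At least two beats (one defined IBI).
    fs:
        Output sampling rate, default 10 Hz (grid spacing exactly 1/fs).
    duration:
        Length of the output grid in seconds; defaults to the last beat
        time.  The grid starts at t = 0 of the recording.
    """
    if fs <= 0:
        raise ArgumentError("fs must be positive")
    if len(beats) < 2:
        raise ArgumentError("need at least 2 beats (one defined IBI)")
    anchor_t = beats.beat_times[1:]
    anchor_v = beats.ibis[1:]
    if duration is None:
        duration = float(beats.beat_times[-1])
    n = int(np.floor(duration * fs + 1e-9)) + 1
    t = np.arange(n) / fs
    values = np.interp(t, anchor_t, anchor_v)  # constant beyond the anchors
    return HeartPeriodSeries(values, fs=fs, start_time=0.0, filtered=False)


def bandpass_sos(fs: float) -> np.ndarray:
    """Second-order sections of the 0.01-2 Hz Butterworth band-pass."""
    return sps.butter(2, BANDPASS, btype="bandpass", fs=fs, output="sos")


def bandpass_heart_period(hp: HeartPeriodSeries) -> HeartPeriodSeries:
    """Apply the 0.01-2 Hz band-pass (zero-phase) to an unfiltered series.

    The output is mean-free over long records (DC is removed); applying the
    filter twice is refused because the effective response would no longer
    match the model's.
    """
    if hp.filtered:
        raise ArgumentError("series is already filtered; refusing to filter twice")
    if hp.fs <= 4.0:
        raise ArgumentError(
            f"sampling rate must exceed 4 Hz for the 2 Hz corner, got {hp.fs}"
        )
    values = sps.sosfiltfilt(bandpass_sos(hp.fs), hp.values)
    return HeartPeriodSeries(
        values, fs=hp.fs, start_time=hp.start_time, filtered=True
    )
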