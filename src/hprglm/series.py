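"""Core time-series containers: ECG, beat trains, and heart-period series.

Conventions
-----------
* Time is in seconds from the start of the recording (``t = 0``).
* Heart period and interbeat intervals (IBIs) are in milliseconds.
* Each IBI is assigned to its *following* heartbeat, so the first beat of a
  record has no IBI (stored as NaN).
* Cardiac *deceleration* means a longer heart period, *acceleration* a
  shorter one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ArgumentError

FLAG_OK = "ok"
FLAG_OUTLIER = "outlier"
FLAG_CORRECTED = "corrected"
VALID_FLAGS = (FLAG_OK, FLAG_OUTLIER, FLAG_CORRECTED)


@dataclass(frozen=True)
class ECGSignal:
    """A single-channel ECG trace.

    Parameters
    ----------
    samples:
        Voltage samples in arbitrary units.
    fs:
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ArgumentError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ArgumentError("ECG samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ArgumentError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def to_csv(self, path: str | Path, seed: int | None = None) -> None:
        """Write as two-column delimited text plus a JSON sidecar."""
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "value": self.samples}).to_csv(
            path, index=False
        )
        sidecar = {"fs": self.fs, "units": "a.u.", "seed": seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "ECGSignal":
        """Read the two-column text format; ``fs`` overrides the sidecar."""
        path = Path(path)
        frame = pd.read_csv(path)
        if fs is None:
            sidecar = path.with_suffix(".json")
            if sidecar.exists():
                fs = json.loads(sidecar.read_text())["fs"]
            else:
                dt = np.diff(frame["time_s"].to_numpy())
                fs = 1.0 / float(np.median(dt))
        return cls(frame["value"].to_numpy(), float(fs))


@dataclass(frozen=True)
class BeatTimeSeries:
    """Detected or simulated heartbeat times with per-beat IBIs and flags.

    ``ibis[i]`` is ``(beat_times[i] - beat_times[i-1]) * 1000`` for ``i >= 1``;
    the first entry is NaN because the first beat has no preceding beat.
    """

    beat_times: np.ndarray
    ibis: np.ndarray = field(default=None)  # type: ignore[assignment]
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", times)
        if times.ndim != 1:
            raise ArgumentError("beat times must be one-dimensional")
        if times.size and np.any(np.diff(times) <= 0):
            raise ArgumentError("beat times must be strictly increasing")
        if self.ibis is None:
            object.__setattr__(self, "ibis", _ibis_from_times(times))
        else:
            ibis = np.asarray(self.ibis, dtype=float)
            expected = _ibis_from_times(times)
            if ibis.shape != times.shape or not np.allclose(
                ibis[1:], expected[1:], atol=1e-9, equal_nan=True
            ):
                raise ArgumentError("IBIs inconsistent with beat times")
            object.__setattr__(self, "ibis", ibis)
        if self.flags is None:
            object.__setattr__(
                self, "flags", np.full(times.shape, FLAG_OK, dtype="<U9")
            )
        else:
            flags = np.asarray(self.flags, dtype="<U9")
            if flags.shape != times.shape:
                raise ArgumentError("flags must have one entry per beat")
            if times.size and not np.isin(flags, VALID_FLAGS).all():
                raise ArgumentError(f"flags must be one of {VALID_FLAGS}")
            object.__setattr__(self, "flags", flags)

    def __len__(self) -> int:
        return self.beat_times.size

    def with_flags(self, flags: np.ndarray) -> "BeatTimeSeries":
        return replace(self, flags=np.asarray(flags, dtype="<U9"))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "ibi_ms": self.ibis,
                "flag": self.flags,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BeatTimeSeries":
        frame = pd.read_csv(path)
        flags = (
            frame["flag"].to_numpy(dtype="<U9")
            if "flag" in frame
            else None
        )
        return cls(frame["beat_time_s"].to_numpy(), flags=flags)


def _ibis_from_times(times: np.ndarray) -> np.ndarray:
    ibis = np.full(times.shape, np.nan)
    if times.size >= 2:
        ibis[1:] = np.diff(times) * 1000.0
    return ibis


@dataclass(frozen=True)
class HeartPeriodSeries:
    """Evenly sampled heart-period signal.

    ``values`` are in milliseconds (after band-pass filtering they are
    deviations around zero).  The canonical sampling rate is 10 Hz.  The
    sample grid is anchored at ``start_time`` (normally 0 s of the recording)
    so that event onsets and samples share one clock.
    """

    values: np.ndarray
    fs: float = 10.0
    start_time: float = 0.0
    filtered: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.fs <= 0:
            raise ArgumentError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(values)):
            raise ArgumentError("heart-period values must be finite")
        if not self.filtered and values.size and values.min() <= 0:
            raise ArgumentError("unfiltered heart period must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path: str | Path, filter_spec: dict | None = None) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "hp_ms": self.values}).to_csv(
            path, index=False
        )
        sidecar = {
            "fs": self.fs,
            "filtered": self.filtered,
            "filter_spec": filter_spec,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeartPeriodSeries":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            fs = float(sidecar["fs"])
            filtered = bool(sidecar["filtered"])
        else:
            fs = 1.0 / float(np.median(np.diff(frame["time_s"].to_numpy())))
            filtered = bool(np.min(frame["hp_ms"].to_numpy()) <= 0)
        return cls(
            frame["hp_ms"].to_numpy(),
            fs=fs,
            start_time=float(frame["time_s"].iloc[0]),
            filtered=filtered,
        )
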