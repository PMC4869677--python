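"""Operational peak scoring of event-related heart period responses.

Implements the classic windowed protocol: a baseline mean B over [-1, 0) s
before the event, then window extrema of the heart period — primary
deceleration D1 (maximum over [0, 2] s), acceleration A (minimum over
[2, 5] s), and secondary deceleration D2 (maximum over [5, 8] s) — with the
five derived difference indices and peak deceleration/acceleration from
baseline over the whole trial window.

Everything is in heart-period units (ms): deceleration means a longer
period, so decelerations score positive relative to baseline and
accelerations negative.  Window boundaries are half-open at the baseline
(-1 <= t < 0) and closed for the response windows, whose shared endpoints
(t = 2, t = 5) belong to both neighbouring windows; ties there are
harmless because only window extrema enter the indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventSchedule
from .exceptions import ArgumentError, ScoringError
from .series import HeartPeriodSeries

#: Scoring windows in seconds relative to onset.
BASELINE_WINDOW = (-1.0, 0.0)  # [lo, hi)
D1_WINDOW = (0.0, 2.0)  # closed
A_WINDOW = (2.0, 5.0)  # closed
D2_WINDOW = (5.0, 8.0)  # closed
DEFAULT_TRIAL_END = 8.0


@dataclass(frozen=True)
class PeakScores:
    """The seven operational indices of one trial (all ms)."""

    B: float
    D1: float
    A: float
    D2: float
    b_d1: float  # B - D1: primary deceleration
    a_b: float  # A - B: acceleration
    b_d2: float  # B - D2: secondary deceleration
    a_d1: float  # A - D1
    a_d2: float  # A - D2
    peak_deceleration: float  # max(hp) - B over the trial window
    peak_acceleration: float  # min(hp) - B over the trial window

    def as_dict(self) -> dict[str, float]:
        return {
            "B": self.B,
            "D1": self.D1,
            "A": self.A,
            "D2": self.D2,
            "B-D1": self.b_d1,
            "A-B": self.a_b,
            "B-D2": self.b_d2,
            "A-D1": self.a_d1,
            "A-D2": self.a_d2,
            "peak_deceleration": self.peak_deceleration,
            "peak_acceleration": self.peak_acceleration,
        }


def score_trial(
    values: np.ndarray,
    times: np.ndarray,
    trial_end: float = DEFAULT_TRIAL_END,
) -> PeakScores:
    """Score one epoch given its heart-period values and onset-relative times.

    The epoch must cover at least [-1, +8] s with uniform sampling; NaN
    inside any scoring window raises :class:`ScoringError`.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ArgumentError("values and times must align")
    if times.size < 2 or times[0] > BASELINE_WINDOW[0] or times[-1] < max(
        D2_WINDOW[1], trial_end
    ):
        raise ArgumentError(
            f"epoch must cover [-1, {max(D2_WINDOW[1], trial_end)}] s"
        )

    def window(lo: float, hi: float, closed_right: bool = True) -> np.ndarray:
        mask = (times >= lo) & ((times <= hi) if closed_right else (times < hi))
        vals = values[mask]
        if vals.size == 0:
            raise ArgumentError(f"no samples in window [{lo}, {hi}] s")
        if np.any(np.isnan(vals)):
            raise ScoringError(f"NaN inside scoring window [{lo}, {hi}] s")
        return vals

    B = float(np.mean(window(*BASELINE_WINDOW, closed_right=False)))
    D1 = float(np.max(window(*D1_WINDOW)))
    A = float(np.min(window(*A_WINDOW)))
    D2 = float(np.max(window(*D2_WINDOW)))
    trial = window(0.0, trial_end)
    return PeakScores(
        B=B,
        D1=D1,
        A=A,
        D2=D2,
        b_d1=B - D1,
        a_b=A - B,
        b_d2=B - D2,
        a_d1=A - D1,
        a_d2=A - D2,
        peak_deceleration=float(np.max(trial)) - B,
        peak_acceleration=float(np.min(trial)) - B,
    )


def score_schedule(
    hp: HeartPeriodSeries,
    schedule: EventSchedule,
    trial_end: float = DEFAULT_TRIAL_END,
) -> pd.DataFrame:
    """Score every trial of a session; returns a tidy per-trial table.

    Trials whose scoring window is not fully inside the record are skipped.
    """
    rows = []
    for k, (onset, condition) in enumerate(
        zip(schedule.onsets, schedule.conditions)
    ):
        rel = hp.times - onset
        mask = (rel >= BASELINE_WINDOW[0] - 1e-9) & (
            rel <= max(D2_WINDOW[1], trial_end) + 1e-9
        )
        if not mask.any():
            continue
        try:
            scores = score_trial(hp.values[mask], rel[mask], trial_end=trial_end)
        except ArgumentError:
            continue
        rows.append({"trial": k, "condition": condition, **scores.as_dict()})
    return pd.DataFrame(rows)


def condition_means(per_trial: pd.DataFrame) -> pd.DataFrame:
    """Average per-trial scores within condition."""
    return per_trial.drop(columns="trial").groupby("condition").mean()
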