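"""Event schedules and the four experimental designs.

The designs mirror classic event-related cardiac paradigms with brief (1 s)
stimuli:

``exp1``
    Aversive white-noise bursts, intertrial interval (ITI) drawn uniformly
    from {29, 34, 39} s; a single event type.
``exp2_oddball``
    Auditory oddball; the modelled events are the rare oddball tones, whose
    ITIs are likewise drawn from {29, 34, 39} s.
``exp3``
    Emotional picture viewing (neutral / positive / negative), ITI drawn
    from {43, 45, 47} s.
``exp4``
    Short-ITI validation design (negative / positive pictures, loud / soft
    sounds) with ITIs uniform on [4, 16] s (10 s +/- 6 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, ConfigurationError

#: Maximum temporal support of a response function in seconds (from 5 s
#: before the event to 30 s after); schedules leave this much room after the
#: last onset so every epoch is complete.
MAX_RF_SUPPORT = 30.0

DESIGNS: dict[str, dict] = {
    "exp1": {"itis": (29.0, 34.0, 39.0), "conditions": ("noise",)},
    "exp2_oddball": {"itis": (29.0, 34.0, 39.0), "conditions": ("oddball",)},
    "exp3": {
        "itis": (43.0, 45.0, 47.0),
        "conditions": ("neutral", "positive", "negative"),
    },
    "exp4": {
        "iti_range": (4.0, 16.0),
        "conditions": ("negative", "positive", "sound85", "sound65"),
    },
}


@dataclass(frozen=True)
class EventSchedule:
    """Stimulus onsets with condition labels for one recording session."""

    onsets: np.ndarray
    conditions: np.ndarray
    session_length: float
    design_name: str = "custom"
    stimulus_duration: float = 1.0
    condition_set: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        conditions = np.asarray(self.conditions, dtype="<U32")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "conditions", conditions)
        if onsets.ndim != 1 or conditions.shape != onsets.shape:
            raise ArgumentError("onsets and conditions must be 1-d and aligned")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ArgumentError("onsets must be strictly increasing")
        if not self.condition_set:
            object.__setattr__(
                self, "condition_set", tuple(dict.fromkeys(conditions.tolist()))
            )
        unknown = set(conditions.tolist()) - set(self.condition_set)
        if unknown:
            raise ArgumentError(f"conditions {unknown} not in declared set")
        if onsets.size and onsets[-1] + MAX_RF_SUPPORT > self.session_length:
            raise ArgumentError(
                "session too short: the last onset leaves less than "
                f"{MAX_RF_SUPPORT} s of post-event recording"
            )

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def itis(self) -> np.ndarray:
        """Consecutive onset differences in seconds."""
        return np.diff(self.onsets)

    @property
    def min_iti(self) -> float:
        return float(self.itis.min()) if len(self) > 1 else np.inf

    def onsets_for(self, condition: str) -> np.ndarray:
        return self.onsets[self.conditions == condition]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"onset_s": self.onsets, "condition": self.conditions}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, session_length: float | None = None
    ) -> "EventSchedule":
        frame = pd.read_csv(path)
        onsets = frame["onset_s"].to_numpy(dtype=float)
        if session_length is None:
            session_length = (onsets[-1] + MAX_RF_SUPPORT) if onsets.size else 0.0
        return cls(
            onsets,
            frame["condition"].to_numpy(dtype="<U32"),
            session_length=float(session_length),
        )


def generate_schedule(
    design_name: str,
    n_events: int,
    seed: int,
    lead_in: float = 20.0,
) -> EventSchedule:
    """Draw a reproducible event schedule for one of the four designs.

    ITIs are drawn uniformly from the design's discrete set (or uniformly on
    the continuous range for ``exp4``); condition labels are balanced across
    the event sequence by shuffling repeated blocks of the condition set.

    Parameters
    ----------
    design_name:
        One of ``exp1``, ``exp2_oddball``, ``exp3``, ``exp4``.
    n_events:
        Number of events; 0 yields an empty schedule.
    seed:
        Seed for the ITI and condition draws.
    lead_in:
        Time of the first onset, seconds.  Must exceed the 5 s prestimulus
        support of the response functions plus the 2 s epoch margin.
    """
    if design_name not in DESIGNS:
        raise ConfigurationError(
            f"unknown design {design_name!r}; choose from {sorted(DESIGNS)}"
        )
    if n_events < 0:
        raise ArgumentError(f"n_events must be non-negative, got {n_events}")
    design = DESIGNS[design_name]
    rng = np.random.default_rng(seed)

    if n_events == 0:
        return EventSchedule(
            np.empty(0),
            np.empty(0, dtype="<U32"),
            session_length=lead_in,
            design_name=design_name,
            condition_set=design["conditions"],
        )

    if "itis" in design:
        itis = rng.choice(design["itis"], size=n_events - 1)
    else:
        lo, hi = design["iti_range"]
        itis = rng.uniform(lo, hi, size=n_events - 1)
    onsets = lead_in + np.concatenate([[0.0], np.cumsum(itis)])

    # Balanced condition assignment: shuffle whole blocks of the label set.
    labels = design["conditions"]
    n_blocks = int(np.ceil(n_events / len(labels)))
    pool = np.array(labels * n_blocks, dtype="<U32")
    rng.shuffle(pool)
    conditions = pool[:n_events]

    return EventSchedule(
        onsets,
        conditions,
        session_length=float(onsets[-1] + MAX_RF_SUPPORT + 1.0),
        design_name=design_name,
        condition_set=labels,
    )
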