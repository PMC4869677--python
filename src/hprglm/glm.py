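"""Convolution GLM: design-matrix construction and least-squares inversion.

For each condition, a unit-impulse train at that condition's event onsets
is convolved with every RF shape of the basis, giving one regressor per
(condition x RF) plus an intercept.  Inverting the GLM by ordinary least
squares yields per-condition amplitude estimates for each response
component, in milliseconds (the basis stores unit-peak shapes).

Two practical points this module enforces:

* Regressors are passed through the identical band-pass as the data
  (default on): fitting filtered data with unfiltered regressors biases
  amplitude estimates.
* Onsets are rasterized to the nearest sample of the heart-period grid
  (+/- 50 ms at 10 Hz), shifted to honour the 5 s prestimulus support of
  the RFs.

When any RF's effective support (centre + 2 sigma) exceeds the minimum
intertrial interval of the schedule, responses overlap and the linearity
assumption becomes brittle; a :class:`OverlapWarning` is emitted
recommending a basis restricted to RFs that peak within the minimum ITI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .basis import BasisSet
from .events import EventSchedule
from .exceptions import ArgumentError, EstimationError
from .heart_period import bandpass_sos
from .series import HeartPeriodSeries

logger = logging.getLogger(__name__)


class OverlapWarning(UserWarning):
    """An RF's support exceeds the minimum intertrial interval."""


@dataclass(frozen=True)
class DesignMatrix:
    """Regressors for the convolution GLM (intercept in the last column)."""

    X: np.ndarray
    labels: tuple[str, ...]
    conditions: tuple[str, ...]
    n_rfs: int
    fs: float
    filtered_like_data: bool
    condition_n: dict[str, int]
    truncated_events: int = 0

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.labels):
            raise ArgumentError("labels must match design columns")
        if len(set(self.labels)) != len(self.labels):
            raise ArgumentError("design column labels must be unique")
        nonzero = np.any(self.X != 0, axis=0)
        if not nonzero.all():
            dead = [l for l, nz in zip(self.labels, nonzero) if not nz]
            raise ArgumentError(f"all-zero regressor column(s): {dead}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def build_design_matrix(
    schedule: EventSchedule,
    basis: BasisSet,
    n_samples: int,
    fs: float,
    filtered_like_data: bool = True,
) -> DesignMatrix:
    """Build the convolution design matrix for one recording.

    Parameters
    ----------
    schedule:
        Event onsets and condition labels; must be non-empty and within the
        record.
    basis:
        RF basis sampled at ``fs``.
    n_samples:
        Number of rows; must equal the heart-period sample count.
    filtered_like_data:
        Pass every regressor through the same 0.01-2 Hz zero-phase
        band-pass as the data (recommended and default).
    """
    if len(schedule) == 0:
        raise ArgumentError("empty schedule: no events to model")
    if basis.fs != fs:
        raise ArgumentError(
            f"basis sampled at {basis.fs} Hz but design requested at {fs} Hz"
        )
    if np.any(schedule.onsets * fs > n_samples - 1):
        raise ArgumentError("event onset beyond the end of the record")

    min_iti = schedule.min_iti
    if basis.max_support_end > min_iti:
        warnings.warn(
            f"RF support extends to {basis.max_support_end:.1f} s but the "
            f"minimum ITI is {min_iti:.1f} s: responses overlap; consider "
            "a basis restricted to RFs that peak within the minimum ITI",
            OverlapWarning,
            stacklevel=2,
        )

    conditions = tuple(sorted(set(schedule.conditions.tolist())))
    shapes = basis.shapes
    offset = round(5.0 * fs)  # prestimulus support of the RF shapes
    truncated = 0
    columns, labels = [], []
    for condition in conditions:
        onsets = schedule.onsets_for(condition)
        for j in range(len(basis)):
            shape = shapes[j]
            reg = np.zeros(n_samples)
            for onset in onsets:
                i0 = round(onset * fs) - offset
                lo, hi = max(0, i0), min(n_samples, i0 + shape.size)
                if hi - lo < shape.size:
                    truncated += 1
                reg[lo:hi] += shape[lo - i0 : hi - i0]
            columns.append(reg)
            labels.append(f"{condition}:{basis.rfs[j].label or f'RF{j + 1}'}")
    if truncated:
        logger.warning(
            "%d regressor placements truncated at the record edges", truncated
        )
    design = np.column_stack(columns)
    if filtered_like_data:
        design = sps.sosfiltfilt(bandpass_sos(fs), design, axis=0)
    design = np.column_stack([design, np.ones(n_samples)])
    labels.append("intercept")
    condition_n = {
        c: int(np.sum(schedule.conditions == c)) for c in conditions
    }
    return DesignMatrix(
        X=design,
        labels=tuple(labels),
        conditions=conditions,
        n_rfs=len(basis),
        fs=fs,
        filtered_like_data=filtered_like_data,
        condition_n=condition_n,
        truncated_events=truncated,
    )


@dataclass(frozen=True)
class GLMFit:
    """Ordinary-least-squares fit of the convolution GLM."""

    amplitudes: dict[str, float]  # label -> coefficient (ms)
    intercept: float
    residual_variance: float
    fitted: HeartPeriodSeries
    residuals: np.ndarray
    design: DesignMatrix

    def amplitude(self, condition: str, rf_index: int) -> float:
        """Coefficient for ``condition`` and the (0-based) RF index."""
        label = self.design.labels[
            self.design.conditions.index(condition) * self.design.n_rfs + rf_index
        ]
        return self.amplitudes[label]

    def condition_amplitudes(self, condition: str) -> np.ndarray:
        """All RF coefficients of one condition, in basis order."""
        return np.array(
            [self.amplitude(condition, j) for j in range(self.design.n_rfs)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(condition, RF) amplitude table."""
        rows = [
            {
                "condition": c,
                "rf_index": j + 1,
                "estimate_ms": self.amplitude(c, j),
            }
            for c in self.design.conditions
            for j in range(self.design.n_rfs)
        ]
        return pd.DataFrame(rows)


def fit_glm(hp: HeartPeriodSeries, design: DesignMatrix) -> GLMFit:
    """Invert the convolution GLM by ordinary least squares.

    Requires a band-pass-filtered heart-period series whose sample count
    matches the design.  A rank-deficient design raises
    :class:`EstimationError` naming the dependent column(s).
    """
    if not hp.filtered:
        raise ArgumentError("heart-period series must be band-pass filtered")
    if len(hp) != design.n_samples:
        raise ArgumentError(
            f"series has {len(hp)} samples but design has {design.n_samples} rows"
        )
    X, y = design.X, hp.values
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # Identify dependent columns via the pivoted QR decomposition.
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dependent = [design.labels[piv[i]] for i in range(rank, X.shape[1])]
        raise EstimationError(
            f"rank-deficient design matrix; dependent column(s): {dependent}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted_values = X @ beta
    residuals = y - fitted_values
    dof = max(1, X.shape[0] - X.shape[1])
    amplitudes = dict(zip(design.labels[:-1], beta[:-1].tolist()))
    return GLMFit(
        amplitudes=amplitudes,
        intercept=float(beta[-1]),
        residual_variance=float(residuals @ residuals / dof),
        fitted=HeartPeriodSeries(
            fitted_values, fs=hp.fs, start_time=hp.start_time, filtered=True
        ),
        residuals=residuals,
        design=design,
    )
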