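"""Response-function basis development from epoched heart-period data.

The development pipeline mirrors how the canonical basis was derived:

1. Epoch band-pass-filtered heart-period data from 2 s before to 29 s
   after each event onset and mean-centre every epoch.
2. Run a PCA over all epochs from all participants; keep the leading
   components.
3. Model every individual peak (maxima and minima) of the retained
   component waveforms as a Gaussian, giving a pool of candidate RFs.
4. Qualify and select candidates stepwise: each candidate must either show
   a stable response direction across all experiments (one-sample t test)
   or separate the experiments (between-subjects ANOVA); the set is then
   grown chronologically, orthogonalizing each candidate set in temporal
   order and retaining an added RF only if it separates the experiments.

Statistical machinery (t tests, ANOVA) comes from :mod:`scipy.stats`; the
PCA is a plain SVD of the row-centred epoch matrix, since the epochs are
centred per row rather than per time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps, stats

from .basis import (
    BasisSet,
    GaussianComponent,
    ResponseFunction,
    gram_schmidt_basis,
)
from .events import EventSchedule
from .exceptions import ArgumentError, SelectionError
from .glm import build_design_matrix, fit_glm
from .series import HeartPeriodSeries

logger = logging.getLogger(__name__)

#: Epoch window relative to event onset, seconds.
EPOCH_WINDOW = (-2.0, 29.0)


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's filtered heart-period record and event schedule."""

    participant: str
    hp: HeartPeriodSeries
    schedule: EventSchedule
    experiment: str


@dataclass(frozen=True)
class EpochMatrix:
    """Mean-centred event-locked epochs, one row per retained event."""

    data: np.ndarray
    participants: np.ndarray
    experiments: np.ndarray
    conditions: np.ndarray
    fs: float
    centered: bool = True
    n_dropped: int = 0

    def __post_init__(self) -> None:
        expected = epoch_length(self.fs)
        if self.data.ndim != 2 or self.data.shape[1] != expected:
            raise ArgumentError(
                f"epoch rows must have {expected} samples at {self.fs} Hz"
            )

    @property
    def times(self) -> np.ndarray:
        """Epoch time axis relative to onset, seconds."""
        return EPOCH_WINDOW[0] + np.arange(self.data.shape[1]) / self.fs

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def epoch_length(fs: float) -> int:
    """Samples per epoch, both window endpoints included."""
    return round((EPOCH_WINDOW[1] - EPOCH_WINDOW[0]) * fs) + 1


def epoch_and_center(
    hp: HeartPeriodSeries,
    schedule: EventSchedule,
    participant: str = "p00",
    experiment: str = "exp",
) -> EpochMatrix:
    """Extract [-2, +29] s epochs around each onset and mean-centre them.

    Events whose window is not fully inside the record are dropped (the
    count is logged and recorded on the result).  Raises if no epoch
    survives.
    """
    if not hp.filtered:
        raise ArgumentError("epoching expects a band-pass-filtered series")
    fs = hp.fs
    pre = round(-EPOCH_WINDOW[0] * fs)
    post = round(EPOCH_WINDOW[1] * fs)
    rows, conditions = [], []
    dropped = 0
    for onset, condition in zip(schedule.onsets, schedule.conditions):
        i_on = round((onset - hp.start_time) * fs)
        lo, hi = i_on - pre, i_on + post + 1
        if lo < 0 or hi > len(hp):
            dropped += 1
            continue
        row = hp.values[lo:hi]
        rows.append(row - row.mean())
        conditions.append(condition)
    if dropped:
        logger.info("dropped %d events with incomplete epoch windows", dropped)
    if not rows:
        raise ArgumentError("no epoch fully inside the record")
    data = np.vstack(rows)
    n = data.shape[0]
    return EpochMatrix(
        data=data,
        participants=np.full(n, participant, dtype="<U32"),
        experiments=np.full(n, experiment, dtype="<U32"),
        conditions=np.asarray(conditions, dtype="<U32"),
        fs=fs,
        n_dropped=dropped,
    )


def concat_epochs(matrices: list[EpochMatrix]) -> EpochMatrix:
    """Stack epoch matrices from several participants/experiments."""
    if not matrices:
        raise ArgumentError("nothing to concatenate")
    fs = matrices[0].fs
    if any(m.fs != fs for m in matrices):
        raise ArgumentError("epoch matrices must share one sampling rate")
    return EpochMatrix(
        data=np.vstack([m.data for m in matrices]),
        participants=np.concatenate([m.participants for m in matrices]),
        experiments=np.concatenate([m.experiments for m in matrices]),
        conditions=np.concatenate([m.conditions for m in matrices]),
        fs=fs,
        n_dropped=sum(m.n_dropped for m in matrices),
    )


@dataclass(frozen=True)
class PCAResult:
    """Leading principal components of the epoch matrix."""

    component_waveforms: np.ndarray  # (n_keep, n_times)
    explained_fraction: np.ndarray  # (n_keep,)
    explained_fraction_all: np.ndarray  # full spectrum, sums to 1
    epoch_scores: np.ndarray  # (n_epochs, n_keep)
    participant_loadings: pd.DataFrame  # participants x components
    times: np.ndarray


def pca_epochs(epochs: EpochMatrix, n_keep: int = 3) -> PCAResult:
    """PCA over all epochs: SVD of the row-centred epoch matrix.

    Component waveforms are the right singular vectors (time courses);
    explained fractions are the normalized squared singular values; epoch
    scores are the projections of each epoch onto the components, and
    participant loadings their per-participant means.  Component signs are
    fixed so each waveform's largest-magnitude sample is positive.
    """
    if not epochs.centered:
        raise ArgumentError("epochs must be mean-centred")
    if n_keep < 1:
        raise ArgumentError("n_keep must be at least 1")
    X = epochs.data
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_keep > rank:
        raise ArgumentError(f"n_keep={n_keep} exceeds matrix rank {rank}")
    explained_all = s**2 / np.sum(s**2)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = X @ Vt[:n_keep].T
    loadings = (
        pd.DataFrame(
            scores,
            columns=[f"PC{k + 1}" for k in range(n_keep)],
        )
        .assign(participant=epochs.participants)
        .groupby("participant")
        .mean()
    )
    return PCAResult(
        component_waveforms=Vt[:n_keep],
        explained_fraction=explained_all[:n_keep],
        explained_fraction_all=explained_all,
        epoch_scores=scores,
        participant_loadings=loadings,
        times=epochs.times,
    )


def elbow_n_keep(explained_fraction_all: np.ndarray, default: int = 3) -> int:
    """Largest-drop elbow rule for the number of components to keep.

    A programmatic stand-in for visual scree-plot inspection: keep the
    components before the largest drop in explained fraction (never fewer
    than one).  ``default`` caps the suggestion.
    """
    frac = np.asarray(explained_fraction_all)
    if frac.size < 2:
        return 1
    drops = frac[:-1] - frac[1:]
    return int(min(default, np.argmax(drops) + 1))


def _gaussian(t, a, mu, sigma):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_peaks(
    waveform: np.ndarray,
    times: np.ndarray,
    prominence_frac: float = 0.1,
) -> list[GaussianComponent]:
    """Model each peak of a component waveform as a Gaussian.

    Local maxima and minima with prominence above ``prominence_frac`` times
    the waveform's maximum absolute value are identified; minima are fitted
    with negative amplitude.  Each Gaussian is least-squares-fitted on a
    neighbourhood bounded by the adjacent zero crossings and extrema, and
    the components are returned in ascending centre order.  A flat
    waveform yields an empty list.
    """
    w = np.asarray(waveform, dtype=float)
    t = np.asarray(times, dtype=float)
    if w.shape != t.shape:
        raise ArgumentError("waveform and time axis must align")
    scale = np.max(np.abs(w)) if w.size else 0.0
    if scale == 0.0:
        return []
    prominence = prominence_frac * scale
    maxima, _ = sps.find_peaks(w, prominence=prominence)
    minima, _ = sps.find_peaks(-w, prominence=prominence)
    extrema = np.sort(np.concatenate([maxima, minima]))
    if extrema.size == 0:
        return []
    zero_crossings = np.flatnonzero(np.diff(np.signbit(w)))
    boundaries = np.unique(np.concatenate([[0], zero_crossings, extrema, [w.size - 1]]))

    components = []
    for p in extrema:
        lo = boundaries[boundaries < p]
        hi = boundaries[boundaries > p]
        lo = int(lo[-1]) if lo.size else 0
        hi = int(hi[0]) if hi.size else w.size - 1
        sl = slice(lo, hi + 1)
        # Initial width from the half-prominence width of the peak.
        widths, *_ = sps.peak_widths(
            w if p in maxima else -w, [p], rel_height=0.5
        )
        sigma0 = max(0.1, float(widths[0]) / (2.355 * 10) * (t[1] - t[0]) * 10)
        p0 = (w[p], t[p], sigma0)
        try:
            popt, _ = optimize.curve_fit(
                _gaussian,
                t[sl],
                w[sl],
                p0=p0,
                bounds=(
                    (-np.inf, max(-5.0, t[0] - 1.0), 0.05),
                    (np.inf, min(29.0, t[-1] + 1.0), 30.0),
                ),
                maxfev=5000,
            )
            a, mu, sigma = popt
        except RuntimeError:
            a, mu, sigma = p0
        components.append(GaussianComponent(float(a), float(mu), float(sigma)))
    components.sort(key=lambda c: c.center)
    return components


@dataclass(frozen=True)
class QualificationResult:
    """Decision record of the RF qualification test."""

    stable_direction: bool
    direction: str  # "+", "-", or "n.s."
    t_statistic: float
    t_p: float
    separates_conditions: bool
    f_statistic: float
    anova_p: float
    retained: bool


def qualify_rf(
    estimates: dict[str, np.ndarray], alpha: float = 0.05
) -> QualificationResult:
    """Qualify an RF from per-participant amplitude estimates per experiment.

    The RF is retained if its estimates show a stable response direction
    pooled across all experiments (one-sample t test against zero) or
    separate the experiments (one-way between-subjects ANOVA), each at
    level ``alpha``.
    """
    groups = [np.asarray(v, dtype=float) for v in estimates.values()]
    if len(groups) < 1 or any(g.size < 2 for g in groups):
        raise ArgumentError("every experiment needs at least 2 participants")
    pooled = np.concatenate(groups)
    t_stat, t_p = stats.ttest_1samp(pooled, 0.0)
    stable = bool(t_p < alpha)
    if len(groups) >= 2:
        f_stat, f_p = stats.f_oneway(*groups)
    else:
        f_stat, f_p = np.nan, 1.0
    separates = bool(f_p < alpha)
    return QualificationResult(
        stable_direction=stable,
        direction=("+" if pooled.mean() > 0 else "-") if stable else "n.s.",
        t_statistic=float(t_stat),
        t_p=float(t_p),
        separates_conditions=separates,
        f_statistic=float(f_stat),
        anova_p=float(f_p),
        retained=stable or separates,
    )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the stepwise RF selection."""

    basis: BasisSet
    selected_labels: tuple[str, ...]
    log: tuple[dict, ...] = field(default=())


def _fit_rf_set(
    rfs: list[ResponseFunction],
    datasets: dict[str, list[ParticipantRecord]],
    fs: float,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-participant amplitude estimates for an (orthogonalized) RF set.

    Multi-condition experiments are reduced to one estimate per participant
    and RF by averaging the condition coefficients.
    """
    ordered = sorted(rfs, key=lambda rf: rf.center)
    bset = BasisSet(tuple(ordered), fs=fs)
    if len(ordered) > 1:
        bset = gram_schmidt_basis(bset)
    out: dict[str, dict[str, list[float]]] = {
        rf.label: {exp: [] for exp in datasets} for rf in ordered
    }
    for exp, records in datasets.items():
        for rec in records:
            design = build_design_matrix(rec.schedule, bset, len(rec.hp), fs)
            fit = fit_glm(rec.hp, design)
            for j, rf in enumerate(ordered):
                per_condition = [
                    fit.amplitude(c, j) for c in design.conditions
                ]
                out[rf.label][exp].append(float(np.mean(per_condition)))
    return {
        label: {exp: np.asarray(v) for exp, v in groups.items()}
        for label, groups in out.items()
    }


def stepwise_select(
    candidates: list[ResponseFunction],
    datasets: dict[str, list[ParticipantRecord]],
    fs: float = 10.0,
    alpha: float = 0.05,
    growth_alpha: float | None = None,
) -> SelectionResult:
    """Stepwise selection of the RF basis from candidate components.

    Step 1 tests every candidate alone: fit a single-RF GLM per participant
    and keep the candidate if it qualifies (stable direction or experiment
    separation).  The basis is then grown chronologically: at each step the
    chronologically next untested survivor — and any survivor whose
    centre +/- 2 sigma support overlaps it — competes to join the current
    set; each candidate set is orthogonalized in temporal order, refitted,
    and the added RF with the lowest ANOVA p-value joins if it separates
    the experiments at level ``growth_alpha``.  Selection stops when the
    survivor pool is exhausted.

    Because the growth phase runs one significance test per remaining
    survivor, uncorrected testing at ``alpha`` would admit a spurious
    component in roughly ``1 - (1 - alpha)^m`` of selection runs (m =
    number of spurious survivors).  ``growth_alpha`` therefore defaults to
    the Bonferroni share ``alpha / len(candidates)``, controlling the
    family-wise false-inclusion rate of the whole selection at ``alpha``.
    Pass ``growth_alpha=alpha`` for the uncorrected variant.
    """
    if len(datasets) < 2:
        raise ArgumentError("need at least 2 experiments for selection")
    candidates = sorted(candidates, key=lambda rf: rf.center)
    if growth_alpha is None:
        growth_alpha = alpha / len(candidates)
    log: list[dict] = []

    survivors: list[ResponseFunction] = []
    for rf in candidates:
        ests = _fit_rf_set([rf], datasets, fs)[rf.label]
        qual = qualify_rf(ests, alpha=alpha)
        log.append(
            {
                "step": 1,
                "rf": rf.label,
                "center_s": rf.center,
                "t_p": qual.t_p,
                "anova_p": qual.anova_p,
                "retained": qual.retained,
            }
        )
        if qual.retained:
            survivors.append(rf)
    if not survivors:
        raise SelectionError(
            "no candidate RF qualified in step 1; decision log: " f"{log}"
        )

    current = [survivors[0]]
    log.append({"step": 2, "rf": survivors[0].label, "action": "seed"})
    untested = survivors[1:]
    step = 2
    while untested:
        head = untested[0]
        competing = [head] + [
            rf for rf in untested[1:] if rf.overlaps(head)
        ]
        best_rf, best_p = None, np.inf
        for comp in competing:
            ests = _fit_rf_set(current + [comp], datasets, fs)[comp.label]
            qual = qualify_rf(ests, alpha=growth_alpha)
            log.append(
                {
                    "step": step,
                    "rf": comp.label,
                    "anova_p": qual.anova_p,
                    "separates": qual.separates_conditions,
                }
            )
            if qual.anova_p < best_p:
                best_rf, best_p = comp, qual.anova_p
        if best_p < growth_alpha:
            current.append(best_rf)
            untested.remove(best_rf)
            log.append({"step": step, "rf": best_rf.label, "action": "added"})
        else:
            untested.remove(head)
            log.append({"step": step, "rf": head.label, "action": "rejected"})
        step += 1

    ordered = tuple(sorted(current, key=lambda rf: rf.center))
    basis = gram_schmidt_basis(
        BasisSet(ordered, fs=fs, provenance="stepwise-selection")
    )
    return SelectionResult(
        basis=basis,
        selected_labels=tuple(rf.label for rf in ordered),
        log=tuple(log),
    )
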