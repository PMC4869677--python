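"""End-to-end pipeline: simulate -> detect -> heart period -> GLM / scoring.

A :class:`RunConfig` carries every numeric constant of every stage, with
defaults reproducing the model's stated constants (200 Hz working rate,
10 Hz heart-period rate, 0.01-2 Hz band-pass, [-2, 29] s epochs, the
classic scoring windows, decisive AIC difference 3).  Each run writes its
resolved configuration and a manifest (per-stage status, output hashes,
seeds, timing, warnings) alongside the outputs, so identical configurations
reproduce identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import basis as basis_mod
from .ecg import antialias_downsample, correct_beats, detect_qrs, flag_outlier_ibis
from .events import generate_schedule
from .exceptions import ConfigurationError
from .glm import build_design_matrix, fit_glm
from .heart_period import bandpass_heart_period, beats_to_heart_period
from .scoring import condition_means, score_schedule
from .synthetic import SimulationGroundTruth, generate_beats, generate_ecg, generate_heart_period

DEFAULT_AMPLITUDE_SCALES = {"scale": 1.0}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    design: str = "exp1"
    n_events: int = 20
    seed: int = 0
    out_dir: str = "run-out"
    # Stage toggles
    simulate_ecg: bool = True
    detect: bool = True
    make_hp: bool = True
    run_glm: bool = True
    run_peakscore: bool = True
    # Constants (model defaults)
    ecg_fs: float = 1000.0
    working_fs: float = 200.0
    hp_fs: float = 10.0
    bandpass_hz: tuple[float, float] = (0.01, 2.0)
    epoch_window_s: tuple[float, float] = (-2.0, 29.0)
    delta_aic_decisive: float = 3.0
    ecg_noise_sd: float = 0.05
    correction_policy: str = "interpolate"
    basis: str = "canonical"  # "canonical", "validation", or a JSON path
    # Simulation ground truth
    mean_heart_period_ms: float = 850.0
    rsa_amplitude_ms: float = 30.0
    rsa_frequency_hz: float = 0.25
    drift_amplitude_ms: float = 50.0
    noise_sd_ms: float = 5.0
    condition_amplitude_scales: dict = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_SCALES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.working_fs != 200.0:
            raise ConfigurationError("working rate is fixed at 200 Hz")
        if self.hp_fs <= 4.0:
            raise ConfigurationError("heart-period rate must exceed 4 Hz")
        if self.correction_policy not in ("delete", "interpolate", "none"):
            raise ConfigurationError(
                f"unknown correction policy {self.correction_policy!r}"
            )
        if self.n_events < 1:
            raise ConfigurationError("n_events must be positive")

    def resolve_basis(self) -> basis_mod.BasisSet:
        if self.basis == "canonical":
            return basis_mod.canonical_basis(self.hp_fs)
        if self.basis == "validation":
            return basis_mod.validation_basis(self.hp_fs)
        return basis_mod.BasisSet.from_json(Path(self.basis))


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    stages: dict = field(default_factory=dict)
    hashes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    timing_s: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Writes, under ``config.out_dir``: the resolved configuration, the event
    schedule, simulated ECG (if enabled), detected beats, heart-period
    series, per-(condition, RF) amplitude estimates, per-condition peak
    scores, and the run manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seeds={"master": config.seed})
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    basis = config.resolve_basis()
    rng = np.random.default_rng(config.seed)
    sim_seed = int(rng.integers(0, 2**31 - 1))

    def finish(stage: str, t0: float, *paths: Path) -> None:
        manifest.stages[stage] = "ok"
        manifest.timing_s[stage] = round(time.perf_counter() - t0, 4)
        for p in paths:
            manifest.hashes[p.name] = _hash_file(p)

    try:
        # --- simulate -----------------------------------------------------
        t0 = time.perf_counter()
        schedule = generate_schedule(config.design, config.n_events, sim_seed)
        scale = float(config.condition_amplitude_scales.get("scale", 1.0))
        base_amps = tuple(abs(rf.amplitude) for rf in basis.rfs)
        amplitudes = {
            c: tuple(scale * (1.0 + 0.25 * i) * a for a in base_amps)
            for i, c in enumerate(schedule.condition_set)
        }
        truth = SimulationGroundTruth(
            true_amplitudes=amplitudes,
            mean_heart_period=config.mean_heart_period_ms,
            rsa_amplitude=config.rsa_amplitude_ms,
            rsa_frequency=config.rsa_frequency_hz,
            drift_amplitude=config.drift_amplitude_ms,
            noise_sd=config.noise_sd_ms,
            seed=sim_seed,
        )
        hp_true = generate_heart_period(schedule, basis, truth, fs=config.hp_fs)
        beats_true = generate_beats(hp_true, seed=sim_seed)
        schedule.to_csv(out / "events.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {"amplitudes_ms": {c: list(a) for c, a in amplitudes.items()},
                 "seed": sim_seed},
                indent=2,
            )
        )
        manifest.seeds["simulate"] = sim_seed
        finish("simulate", t0, out / "events.csv", out / "ground_truth.json")

        # --- ECG + detection ---------------------------------------------
        if config.simulate_ecg and config.detect:
            t0 = time.perf_counter()
            ecg = generate_ecg(
                beats_true,
                fs=config.ecg_fs,
                noise_sd=config.ecg_noise_sd,
                seed=sim_seed,
                duration=schedule.session_length,
            )
            ecg.to_csv(out / "ecg.csv", seed=sim_seed)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                beats = detect_qrs(antialias_downsample(ecg))
                beats = correct_beats(
                    flag_outlier_ibis(beats), config.correction_policy
                )
            manifest.warnings += [str(w.message) for w in caught]
            manifest.counts["beats_detected"] = len(beats)
            manifest.counts["beats_flagged"] = int(
                np.sum(beats.flags != "ok")
            )
            beats.to_csv(out / "beats.csv")
            finish("detect", t0, out / "beats.csv")
        else:
            beats = beats_true
            beats.to_csv(out / "beats.csv")
            manifest.stages["detect"] = "skipped"

        # --- heart period -------------------------------------------------
        if config.make_hp:
            t0 = time.perf_counter()
            hp = beats_to_heart_period(
                beats, fs=config.hp_fs, duration=schedule.session_length
            )
            hp_filtered = bandpass_heart_period(hp)
            hp_filtered.to_csv(
                out / "hp.csv",
                filter_spec={"order": 2, "band_hz": list(config.bandpass_hz)},
            )
            finish("hp", t0, out / "hp.csv")
        else:
            manifest.stages["hp"] = "skipped"
            hp_filtered = None

        # --- GLM ----------------------------------------------------------
        if config.run_glm and hp_filtered is not None:
            t0 = time.perf_counter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                design = build_design_matrix(
                    schedule, basis, len(hp_filtered), config.hp_fs
                )
                fit = fit_glm(hp_filtered, design)
            manifest.warnings += [str(w.message) for w in caught]
            fit.to_frame().to_csv(out / "amplitudes.csv", index=False)
            (out / "fit_report.json").write_text(
                json.dumps(
                    {
                        "intercept_ms": fit.intercept,
                        "residual_variance_ms2": fit.residual_variance,
                        "condition_n": design.condition_n,
                        "truncated_events": design.truncated_events,
                    },
                    indent=2,
                )
            )
            finish("glm", t0, out / "amplitudes.csv", out / "fit_report.json")
        else:
            manifest.stages["glm"] = "skipped"

        # --- peak scoring ---------------------------------------------------
        if config.run_peakscore and hp_filtered is not None:
            t0 = time.perf_counter()
            per_trial = score_schedule(hp_filtered, schedule)
            per_trial.to_csv(out / "peak_scores.csv", index=False)
            condition_means(per_trial).to_csv(out / "peak_scores_by_condition.csv")
            finish(
                "peakscore",
                t0,
                out / "peak_scores.csv",
                out / "peak_scores_by_condition.csv",
            )
        else:
            manifest.stages["peakscore"] = "skipped"
    except Exception as err:  # record partial completion before re-raising
        manifest.stages["error"] = f"{type(err).__name__}: {err}"
        manifest.to_json(out / "manifest.json")
        raise

    manifest.to_json(out / "manifest.json")
    return manifest
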