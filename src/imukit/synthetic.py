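"""Seeded synthetic IMU cohorts with the statistical structure the analysis assumes.

The generator emulates wearable-sensor recordings of three rhythmic clinical
tasks — finger-nose-finger (fnf, ~1 Hz reaching), alternating hand movements
(ahm, ~2.5 Hz pronation/supination) and heel-shin (hs, ~0.75 Hz) — at 128 Hz.
Each recording has an active half (the instrumented side performs the task)
and a rest half (the other side performs).  Cerebellar severity, on a
BARS-total-like 0-30 scale, perturbs exactly the signal properties the
downstream features measure: a superimposed tremor above the task band cutoff
whose amplitude grows linearly with severity, and phase irregularity
(Brownian phase jitter) of the task fundamental that also grows with
severity.  A Parkinsonism signature instead places a 4-6 Hz tremor in the
rest half.  Every recording gets its own uniformly random 3-D sensor
orientation so no raw channel is privileged and the PCA projection step is
exercised fresh each time.

The module also draws exact samples from the sticky AR-HMM generative model
(:func:`generate_from_arhmm`) for validating the Gibbs sampler against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .arhmm import ARHMMModel
from .errors import InvalidConfigError, InvalidSizeError
from .recordings import MANIFEST_COLUMNS, IMURecording, RecordingMeta, write_recording
from .seeds import STREAM_RECORDING, STREAM_SESSION, STREAM_SEVERITY, child_rng

TASK_CUTOFF_HZ = {"fnf": 2.0, "ahm": 3.0, "hs": 2.0}
TASK_SENSOR = {"fnf": "wrist", "ahm": "wrist", "hs": "ankle"}
TASK_DURATION_S = {"fnf": 40.0, "ahm": 10.0, "hs": 20.0}  # per side
TASK_FUNDAMENTAL_HZ = {"fnf": 1.0, "ahm": 2.5, "hs": 0.75}
TASKS = ("fnf", "ahm", "hs")
SIDES = ("left", "right")


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    diagnosis: str  # ataxia | parkinsonism | control
    severity: float  # BARS-total-like, 0-30; controls are 0
    age_group: str = "adult"  # pediatric | adult
    n_sessions: int = 1

    def __post_init__(self) -> None:
        if self.diagnosis not in ("ataxia", "parkinsonism", "control"):
            raise InvalidConfigError(f"unknown diagnosis {self.diagnosis!r}")
        if self.diagnosis == "control" and self.severity != 0:
            raise InvalidConfigError("controls must have severity 0")
        if not 0 <= self.severity <= 30:
            raise InvalidConfigError("severity must lie in [0, 30]")
        if self.n_sessions < 1:
            raise InvalidConfigError("n_sessions must be >= 1")


@dataclass(frozen=True)
class MotionConfig:
    """Signal-synthesis knobs for one task.

    ``tremor_gain`` and ``phase_jitter_sd`` are per severity unit; tremor
    amplitude = tremor_gain * severity (half that during rest for ataxia),
    and the fundamental's phase performs a random walk with per-sample
    increment sd = phase_jitter_sd * severity.
    """

    task: str
    fundamental_hz: float
    duration_s: float
    tremor_hz: float = 4.0
    tremor_gain: float = 0.03
    phase_jitter_sd: float = 0.005
    amplitude_jitter_sd: float = 0.0
    noise_sd: float = 0.05
    fs_hz: float = 128.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise InvalidConfigError("duration_s and fs_hz must be positive")
        if self.task not in TASK_CUTOFF_HZ:
            raise InvalidConfigError(f"unknown task {self.task!r}")
        cutoff = TASK_CUTOFF_HZ[self.task]
        if not self.fundamental_hz > 0:
            raise InvalidConfigError("fundamental_hz must be positive")
        if self.fundamental_hz >= cutoff:
            raise InvalidConfigError(
                f"fundamental_hz must lie below the {cutoff} Hz band cutoff for {self.task}"
            )
        if self.tremor_hz <= cutoff:
            raise InvalidConfigError(
                f"tremor_hz must lie above the {cutoff} Hz band cutoff for {self.task}"
            )


def default_config(task: str, **overrides) -> MotionConfig:
    """The study-default :class:`MotionConfig` for a task."""
    cfg = MotionConfig(
        task=task,
        fundamental_hz=TASK_FUNDAMENTAL_HZ[task],
        duration_s=TASK_DURATION_S[task],
    )
    return replace(cfg, **overrides) if overrides else cfg


def _smooth_envelope(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Slow (~1 Hz knot) multiplicative amplitude modulation around 1."""
    if sd == 0 or n == 0:
        return np.ones(n)
    n_knots = max(int(np.ceil(n / fs)) + 2, 4)
    knots = rng.normal(0.0, sd, n_knots)
    x = np.linspace(0, n_knots - 1, n)
    return 1.0 + np.interp(x, np.arange(n_knots), knots)


def _oscillation(
    rng: np.random.Generator,
    n: int,
    fs: float,
    freq_hz: float,
    amplitude: float,
    phase_walk_sd: float,
    amp_jitter_sd: float,
) -> np.ndarray:
    t = np.arange(n) / fs
    phase = 2 * np.pi * freq_hz * t
    if phase_walk_sd > 0:
        phase = phase + np.cumsum(rng.normal(0.0, phase_walk_sd, n))
    env = _smooth_envelope(rng, n, fs, amp_jitter_sd)
    return amplitude * env * np.sin(phase)


def generate_recording(
    profile: SubjectProfile,
    config: MotionConfig,
    side: str,
    seed: int | np.random.SeedSequence,
) -> IMURecording:
    """Synthesize one tri-axial accel+gyro recording for one side.

    The right side performs first, so a right-side sensor has its active
    half first and a left-side sensor second.  The 1-D motion lives along a
    uniformly random rotated axis; sensor noise is added per channel after
    rotation.
    """
    if side not in SIDES:
        raise InvalidConfigError(f"side must be one of {SIDES}")
    rng = np.random.default_rng(seed)
    fs = config.fs_hz
    n_half = int(round(config.duration_s * fs))
    n_total = 2 * n_half
    sev = float(profile.severity)

    # task-fundamental oscillation, degraded by severity-scaled jitter
    gyro_active = _oscillation(
        rng,
        n_half,
        fs,
        config.fundamental_hz,
        amplitude=1.0,
        phase_walk_sd=config.phase_jitter_sd * sev,
        amp_jitter_sd=config.amplitude_jitter_sd,
    )
    tremor_amp = config.tremor_gain * sev
    if profile.diagnosis == "ataxia" and tremor_amp > 0:
        gyro_active = gyro_active + _oscillation(
            rng, n_half, fs, config.tremor_hz, tremor_amp, 0.02, 0.0
        )

    # rest half: low-amplitude tremor only (ataxia: half-amplitude action
    # tremor persists; parkinsonism: the 4-6 Hz tremor appears at rest)
    gyro_rest = np.zeros(n_half)
    if profile.diagnosis == "ataxia" and tremor_amp > 0:
        gyro_rest = _oscillation(rng, n_half, fs, config.tremor_hz, 0.5 * tremor_amp, 0.02, 0.0)
    elif profile.diagnosis == "parkinsonism" and sev > 0:
        rest_hz = 5.0  # textbook parkinsonian rest-tremor band midpoint
        gyro_rest = _oscillation(rng, n_half, fs, rest_hz, config.tremor_gain * sev, 0.02, 0.0)

    if side == "right":
        gyro_1d = np.concatenate([gyro_active, gyro_rest])
    else:
        gyro_1d = np.concatenate([gyro_rest, gyro_active])
    # accelerometer carries the same rhythm in quadrature (scaled derivative)
    accel_1d = np.gradient(gyro_1d) * fs / (2 * np.pi * config.fundamental_hz)

    axis = Rotation.random(rng=rng).as_matrix()[:, 0]  # uniformly random unit direction
    gyro = np.outer(gyro_1d, axis)
    accel = np.outer(accel_1d, axis)
    if config.noise_sd > 0:
        gyro = gyro + rng.normal(0.0, config.noise_sd, gyro.shape)
        accel = accel + rng.normal(0.0, config.noise_sd, accel.shape)

    meta = RecordingMeta(
        subject_id=profile.subject_id,
        session_id="?",
        task=config.task,
        side=side,
        sensor=TASK_SENSOR[config.task],
    )
    assert gyro.shape[0] == n_total
    return IMURecording(fs_hz=fs, accel=accel, gyro=gyro, meta=meta)


def _bars_scores(diagnosis: str, severity: float, rng: np.random.Generator):
    """Map a BARS-total-like severity to total + limb subscores.

    Subscores are noisy rescalings of the total (right arm 0-4, arm+leg
    0-16); Parkinsonism sessions carry no BARS scores (scale not applicable).
    """
    if diagnosis == "parkinsonism":
        return np.nan, np.nan, np.nan
    total = float(np.clip(severity, 0.0, 30.0))
    if total == 0:
        return 0.0, 0.0, 0.0
    right_arm = float(np.clip(total * 4 / 30 + rng.normal(0, 0.25), 0, 4))
    arm_leg = float(np.clip(total * 16 / 30 + rng.normal(0, 0.75), 0, 16))
    return total, right_arm, arm_leg


def generate_cohort(
    n_ataxia: int,
    n_control: int,
    n_parkinsonism: int = 0,
    repeat_fraction: float = 0.0,
    seed: int = 0,
    configs: dict[str, MotionConfig] | None = None,
):
    """Generate a full cohort: profiles, recordings and a manifest.

    Every subject-session contributes all 3 tasks x 2 sides (wrist sensor
    for fnf/ahm, ankle for hs).  Ataxia severities are uniform on [1, 20];
    ``repeat_fraction`` of subjects (rounded) get a second session whose
    severity is perturbed by N(0, 1) noise, clipped to the valid range.

    Returns ``(profiles, recordings, manifest)`` where the manifest is a
    DataFrame with one row per recording (path column empty until written).
    """
    if min(n_ataxia, n_control, n_parkinsonism) < 0:
        raise InvalidConfigError("cohort counts must be non-negative")
    if not 0.0 <= repeat_fraction <= 1.0:
        raise InvalidConfigError("repeat_fraction must lie in [0, 1]")
    configs = configs or {task: default_config(task) for task in TASKS}

    sev_rng = child_rng(seed, STREAM_SEVERITY)
    profiles: list[SubjectProfile] = []
    groups = [("ataxia", n_ataxia), ("parkinsonism", n_parkinsonism), ("control", n_control)]
    for diagnosis, count in groups:
        for i in range(count):
            sev = 0.0 if diagnosis == "control" else float(sev_rng.uniform(1.0, 20.0))
            profiles.append(
                SubjectProfile(
                    subject_id=f"{diagnosis[:3]}{i:03d}", diagnosis=diagnosis, severity=sev
                )
            )
    n_subjects = len(profiles)
    n_repeat = int(round(repeat_fraction * n_subjects))
    if n_repeat > 0:
        repeat_idx = sev_rng.choice(n_subjects, size=n_repeat, replace=False)
        for idx in repeat_idx:
            profiles[idx] = replace(profiles[idx], n_sessions=2)

    recordings: list[IMURecording] = []
    rows = []
    counter = 0
    for profile in profiles:
        for visit in range(profile.n_sessions):
            session_id = f"{profile.subject_id}_v{visit + 1}"
            sess_rng = child_rng(seed, STREAM_SESSION, counter)
            if visit == 0 or profile.diagnosis == "control":
                sev = profile.severity
            else:
                lo = 1.0 if profile.diagnosis != "control" else 0.0
                sev = float(np.clip(profile.severity + sess_rng.normal(0.0, 1.0), lo, 30.0))
            bars_total, bars_ra, bars_al = _bars_scores(profile.diagnosis, sev, sess_rng)
            session_profile = replace(profile, severity=sev)
            for task in TASKS:
                for side in SIDES:
                    rec = generate_recording(
                        session_profile,
                        configs[task],
                        side,
                        child_rng(seed, STREAM_RECORDING, counter),
                    )
                    rec.meta.session_id = session_id
                    recordings.append(rec)
                    rows.append(
                        {
                            "subject_id": profile.subject_id,
                            "session_id": session_id,
                            "diagnosis": profile.diagnosis,
                            "severity": sev,
                            "bars_total": bars_total,
                            "bars_right_arm": bars_ra,
                            "bars_arm_leg": bars_al,
                            "task": task,
                            "side": side,
                            "sensor": TASK_SENSOR[task],
                            "path": "",
                        }
                    )
                    counter += 1
            counter += 1  # session-level stream consumed one slot
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return profiles, recordings, manifest


def write_cohort(recordings, manifest: pd.DataFrame, out_dir) -> pd.DataFrame:
    """Write recordings as CSVs under ``out_dir`` and return the manifest with paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    manifest = manifest.copy()
    for i, rec in enumerate(recordings):
        m = rec.meta
        rel = f"recordings/{m.session_id}_{m.task}_{m.side}.csv"
        write_recording(rec, out_dir / rel)
        manifest.loc[manifest.index[i], "path"] = rel
    return manifest


def generate_from_arhmm(model: ARHMMModel, T: int, seed: int | np.random.SeedSequence):
    """Exact forward simulation of the sticky AR-HMM generative model.

    States (1-based labels) follow the Markov chain under the model's
    transition matrix from a uniform initial state; the first ``n_lags``
    observations are standard normal, and each later observation is drawn
    from MVN(A^(x_t) . [y_{t-1}, ..., y_{t-n}], Sigma^(x_t)).

    Returns ``(observations (T, 2), states (T,))``.
    """
    hyper = model.hyper
    n = hyper.n_lags
    L = hyper.L
    if T <= n:
        raise InvalidSizeError(f"T must exceed the AR order n = {n}")
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.trans.pi)
    A = np.asarray(model.dynamics.A)  # (L, 2, 2n)
    chols = np.linalg.cholesky(np.asarray(model.dynamics.Sigma))  # (L, 2, 2)

    states = np.empty(T, dtype=np.int64)
    states[0] = rng.integers(L)
    cum = np.cumsum(pi, axis=1)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")

    y = np.empty((T, 2))
    y[:n] = rng.standard_normal((n, 2))
    z = rng.standard_normal((T, 2))
    for t in range(n, T):
        lags = y[t - n : t][::-1].reshape(-1)  # most recent first
        k = states[t]
        y[t] = A[k] @ lags + chols[k] @ z[t]
    return y, states + 1
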