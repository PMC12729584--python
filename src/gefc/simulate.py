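"""Synthetic SmartGlove-like cohorts for pipeline development and testing.

The real study population (Parkinson's patients recorded OFF and ON
medication with a sensorised glove) is not publicly available, so this
module generates cohorts with the statistical structure the analysis
assumes:

* a 4-6 Hz tremor oscillation whose amplitude and regularity (phase /
  amplitude jitter) are larger OFF medication than ON;
* exercise-specific movement: rest (tremor only), a postural-drift task,
  and two repetitive tasks (finger tapping, hand open-close) whose
  repetition rate is slower OFF (bradykinesia) than ON;
* per-patient random effects (tremor frequency, baseline amplitude, tapping
  ability) giving realistic inter-subject variability;
* three coupled sensors: the accelerometer rides on a gravity offset, the
  gyroscope sees the oscillation's rate with a small bias, and the
  magnetometer is drift-dominated with only attenuated tremor (deliberately
  the least informative channel);
* a random per-session 3-D rotation coupling the axes (the downstream
  magnitude transform is rotation-invariant, so this only shapes per-axis
  realism).

ON/OFF contrast is injected into amplitude, regularity and repetition rate
simultaneously so that spectral, nonlinear and plain statistical features
all carry some signal, with the nonlinear/regularity descriptors carrying
the most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .signal_features import RecordingSession, TriAxialSeries

__all__ = [
    "SimulationConfig",
    "PatientParams",
    "SimulatedCohort",
    "draw_patient_params",
    "simulate_session",
    "generate_cohort",
]

_STATES = ("OFF", "ON")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults give 14 patients, 10-s sessions at 100 Hz (19 windows per
    session under the default 100/50 windowing, hence ~266 windows per class
    per exercise), a 4-6 Hz tremor band, and OFF/ON contrasts in tremor
    amplitude (1.0 vs 0.4), jitter (0.3 vs 0.1) and tap rate (1.5 vs
    2.5 Hz).
    """

    n_patients: int = 14
    fs: float = 100.0
    duration_s: float = 10.0
    tremor_band: tuple[float, float] = (4.0, 6.0)
    tremor_amp_off: float = 1.0
    tremor_amp_on: float = 0.4
    jitter_off: float = 0.3
    jitter_on: float = 0.1
    tap_rate_off: float = 1.5
    tap_rate_on: float = 2.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tremor_amp_on >= self.tremor_amp_off:
            raise ValueError("the contract requires tremor_amp_on < tremor_amp_off")
        for name in ("n_patients", "fs", "duration_s", "tremor_amp_off", "tremor_amp_on",
                     "jitter_off", "jitter_on", "tap_rate_off", "tap_rate_on", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PatientParams:
    """Per-patient random effects drawn once per cohort.

    Tremor amplitude carries both an overall severity and state-specific
    response multipliers: medication response varies strongly between
    patients (a minority barely respond in amplitude), so amplitude-driven
    features are confounded by patient identity while the regularity
    contrast stays consistent — the structure that makes nonlinear
    descriptors the reliable state markers.
    """

    patient_id: str
    index: int
    tremor_freq: float      # Hz, uniform over the tremor band
    amp_scale: float        # multiplicative individual tremor severity
    amp_off_mult: float     # state-specific amplitude response, OFF
    amp_on_mult: float      # state-specific amplitude response, ON
    jitter_mult: float      # mild individual variation in regularity
    tap_scale: float        # multiplicative individual tapping rate


@dataclass(frozen=True)
class SimulatedCohort:
    sessions: tuple[RecordingSession, ...]
    truth: tuple[PatientParams, ...]
    config: SimulationConfig = field(default=None)  # type: ignore[assignment]


def draw_patient_params(cfg: SimulationConfig) -> tuple[PatientParams, ...]:
    out = []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, 7919, i])
        lo, hi = cfg.tremor_band
        out.append(
            PatientParams(
                patient_id=f"P{i:02d}",
                index=i,
                tremor_freq=float(rng.uniform(lo, hi)),
                amp_scale=float(np.exp(rng.normal(0.0, 0.4))),
                amp_off_mult=float(np.exp(rng.normal(0.0, 0.6))),
                amp_on_mult=float(np.exp(rng.normal(0.0, 0.6))),
                jitter_mult=float(np.exp(rng.normal(0.0, 0.2))),
                tap_scale=float(np.exp(rng.normal(0.0, 0.15))),
            )
        )
    return tuple(out)


def _session_rng(cfg: SimulationConfig, patient: PatientParams, exercise: int, state: str):
    return np.random.default_rng([cfg.seed, 104729, patient.index, exercise, _STATES.index(state)])


def simulate_session(
    patient: PatientParams,
    exercise: int,
    state: str,
    cfg: SimulationConfig | None = None,
) -> RecordingSession:
    """One patient x exercise x state recording; bit-identical per seed.

    The accelerometer combines a gravity offset, the jittered tremor
    oscillation, the exercise's task component and white noise; the
    gyroscope carries the oscillation rate with a small bias; the
    magnetometer a slow orientation drift plus attenuated tremor.  A random
    per-session rotation couples the three axes.
    """
    cfg = cfg or SimulationConfig()
    if exercise not in (0, 1, 2, 3):
        raise ValueError("exercise must be in {0,1,2,3}")
    if state not in _STATES:
        raise ValueError("state must be 'OFF' or 'ON'")
    rng = _session_rng(cfg, patient, exercise, state)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    off = state == "OFF"
    amp = patient.amp_scale * (
        cfg.tremor_amp_off * patient.amp_off_mult
        if off
        else cfg.tremor_amp_on * patient.amp_on_mult
    )
    jitter = (cfg.jitter_off if off else cfg.jitter_on) * patient.jitter_mult
    tap_rate = (cfg.tap_rate_off if off else cfg.tap_rate_on) * patient.tap_scale

    # Tremor with phase and amplitude jitter: OFF tremor is larger but also
    # more irregular, which is what the nonlinear descriptors pick up.
    phase_walk = np.cumsum(rng.normal(0.0, jitter * 0.15, size=n))
    amp_mod = 1.0 + jitter * _smooth_noise(rng, n, span=20)
    tremor = amp * amp_mod * np.sin(2 * np.pi * patient.tremor_freq * t + phase_walk)

    task = np.zeros(n)
    if exercise == 1:
        # slow postural drift while holding the arms up
        task = 0.6 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
        task += 0.2 * _smooth_noise(rng, n, span=50)
    elif exercise in (2, 3):
        burst_amp = 2.5 if exercise == 2 else 3.0
        task = burst_amp * _tap_train(rng, t, tap_rate, width_s=0.06)

    tremor_dir = _unit(np.array([0.35, 0.25, 0.9]) + rng.normal(0, 0.05, 3))
    task_dir = _unit(np.array([0.8, 0.5, 0.2]) + rng.normal(0, 0.05, 3))
    # physical gravity magnitude (m/s^2): keeps the accelerometer magnitude in
    # its linear regime, so the tremor fundamental (not a rectification
    # harmonic) dominates the spectrum
    gravity = np.array([0.0, 0.0, 9.81])

    def noise3() -> np.ndarray:
        return rng.normal(0.0, cfg.noise_sd, size=(n, 3))

    acce = (
        gravity[None, :]
        + tremor[:, None] * tremor_dir[None, :]
        + task[:, None] * task_dir[None, :]
        + noise3()
    )

    # angular rate of the oscillation (quadrature phase, frequency-scaled)
    gyro_osc = (
        amp * amp_mod * (2 * np.pi * patient.tremor_freq / 10.0)
        * np.cos(2 * np.pi * patient.tremor_freq * t + phase_walk)
    )
    task_rate = np.gradient(task, 1.0 / cfg.fs) / 10.0
    gyro_bias = np.array([0.3, 0.1, 0.2])
    gyro = (
        gyro_bias[None, :]
        + gyro_osc[:, None] * tremor_dir[None, :]
        + task_rate[:, None] * task_dir[None, :]
        + noise3()
    )

    # magnetometer: slow orientation drift dominates; tremor is attenuated
    drift = np.stack([_smooth_noise(rng, n, span=200) for _ in range(3)], axis=1)
    magn = (
        np.array([0.6, 0.2, 0.8])[None, :]
        + 0.4 * drift
        + 0.15 * tremor[:, None] * tremor_dir[None, :]
        + noise3()
    )

    R = Rotation.random(rng=rng).as_matrix()
    acce, gyro, magn = acce @ R.T, gyro @ R.T, magn @ R.T

    sensors = {
        name: TriAxialSeries(arr[:, 0], arr[:, 1], arr[:, 2], cfg.fs)
        for name, arr in (("acce", acce), ("gyro", gyro), ("magn", magn))
    }
    return RecordingSession(patient.patient_id, exercise, state, sensors)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _smooth_noise(rng: np.random.Generator, n: int, span: int) -> np.ndarray:
    """Zero-mean unit-ish smooth noise: white noise box-filtered over `span`."""
    raw = rng.normal(0.0, 1.0, size=n + span)
    kernel = np.ones(span) / span
    sm = np.convolve(raw, kernel, mode="valid")[:n]
    sd = float(np.std(sm))
    return sm / sd if sd > 0 else sm


def _tap_train(rng: np.random.Generator, t: np.ndarray, rate: float, width_s: float) -> np.ndarray:
    """Gaussian pulse train at ~`rate` Hz with slightly jittered tap times."""
    duration = float(t[-1]) if len(t) > 1 else 0.0
    n_taps = max(1, int(duration * rate))
    times = (np.arange(n_taps) + 0.5) / rate
    times = times + rng.normal(0.0, 0.02 / rate, size=n_taps)
    out = np.zeros_like(t)
    for tk in times:
        out += np.exp(-((t - tk) ** 2) / (2 * width_s**2))
    return out


def generate_cohort(cfg: SimulationConfig | None = None) -> SimulatedCohort:
    """n_patients x 4 exercises x 2 states sessions plus the truth draws."""
    cfg = cfg or SimulationConfig()
    truth = draw_patient_params(cfg)
    sessions = []
    for patient in truth:
        for exercise in range(4):
            for state in _STATES:
                sessions.append(simulate_session(patient, exercise, state, cfg))
    return SimulatedCohort(tuple(sessions), truth, cfg)
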