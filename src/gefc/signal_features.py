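"""Windowed multi-domain feature extraction from tri-axial wearable sensors.

Raw tri-axial accelerometer / gyroscope / magnetometer streams are collapsed
to their per-sample magnitude sqrt(x^2 + y^2 + z^2), sliced into overlapping
sliding windows (default 100 samples = 1 s at 100 Hz, 50% overlap), and each
window is summarised by a fixed bank of 29 features spanning four domains:

* statistical     — central tendency, dispersion, range, distribution shape
                    (mean, median, std, variance, min, max, range, IQR,
                    quartile deviation, skewness, excess kurtosis,
                    coefficient of variation);
* energy          — signal magnitude area, RMS, total energy, log energy;
* spectral        — dominant frequency, flatness, flux, variability, entropy,
                    centroid, spread, 85% roll-off, all from a mean-removed
                    rectangular-window one-sided periodogram;
* nonlinear       — MAD, RMSSD, Higuchi fractal dimension, largest Lyapunov
                    exponent (Rosenstein), sample entropy.

The nonlinear descriptors target the tremor-regularity and movement-
complexity signatures that separate the OFF (pre-medication) and ON
(post-medication) motor states in Parkinson's disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TriAxialSeries",
    "RecordingSession",
    "WindowSpec",
    "FeatureVector",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "SENSOR_NAMES",
    "magnitude_signal",
    "sliding_windows",
    "statistical_features",
    "energy_features",
    "spectral_features",
    "nonlinear_features",
    "window_features",
    "extract_feature_matrix",
]

SENSOR_NAMES = ("acce", "gyro", "magn")

STATISTICAL_NAMES = (
    "mean",
    "median",
    "std",
    "variance",
    "min",
    "max",
    "range",
    "iqr",
    "quartile_deviation",
    "skewness",
    "kurtosis",
    "coefficient_of_variation",
)
ENERGY_NAMES = ("sma", "rms", "total_energy", "log_energy")
SPECTRAL_NAMES = (
    "dominant_frequency",
    "spectral_flatness",
    "spectral_flux",
    "spectral_variability",
    "spectral_entropy",
    "spectral_centroid",
    "spectral_spread",
    "spectral_rolloff",
)
NONLINEAR_NAMES = (
    "mad",
    "rmssd",
    "higuchi_fractal_dimension",
    "lyapunov_exponent",
    "sample_entropy",
)

#: The fixed 29-name feature bank, in extraction order.
FEATURE_NAMES: tuple[str, ...] = (
    STATISTICAL_NAMES + ENERGY_NAMES + SPECTRAL_NAMES + NONLINEAR_NAMES
)

_LOG_ENERGY_EPS = 1e-12
_CV_SENTINEL_EPS = 1e-12


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class TriAxialSeries:
    """One sensor's x/y/z streams sampled at ``fs`` Hz."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        for axis in ("x", "y", "z"):
            object.__setattr__(self, axis, np.asarray(getattr(self, axis), dtype=float))
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if len(self.x) == 0:
            raise ValueError("series must be non-empty")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class RecordingSession:
    """One patient x exercise x medication-state multi-sensor recording."""

    patient_id: str
    exercise: int
    state: str  # "OFF" or "ON"
    sensors: Mapping[str, TriAxialSeries]

    def __post_init__(self) -> None:
        if self.exercise not in (0, 1, 2, 3):
            raise ValueError("exercise must be in {0,1,2,3}")
        if self.state not in ("OFF", "ON"):
            raise ValueError("state must be 'OFF' or 'ON'")
        missing = set(SENSOR_NAMES) - set(self.sensors)
        if missing:
            raise ValueError(f"missing sensors: {sorted(missing)}")
        rates = {self.sensors[s].fs for s in SENSOR_NAMES}
        if len(rates) != 1:
            raise ValueError("all sensors must share the sampling rate")

    @property
    def fs(self) -> float:
        return self.sensors[SENSOR_NAMES[0]].fs

    @property
    def label(self) -> int:
        """Binary medication-state label: 0 = OFF, 1 = ON."""
        return 0 if self.state == "OFF" else 1


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry; defaults give 1-s windows with 50% overlap."""

    length_samples: int = 100
    step_samples: int = 50

    def __post_init__(self) -> None:
        if self.length_samples <= 0 or self.step_samples <= 0:
            raise ValueError("window length and step must be positive")
        if self.step_samples > self.length_samples:
            raise ValueError("step must not exceed window length")


@dataclass(frozen=True)
class FeatureVector:
    """One window's named feature values plus its provenance."""

    values: dict[str, float]
    window_index: int
    source: tuple[str, int, str]  # (patient_id, exercise, state)


@dataclass
class FeatureMatrix:
    """Windows x features with binary state labels (0 = OFF, 1 = ON)."""

    values: pd.DataFrame
    labels: np.ndarray
    patient_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    window_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.values) != len(self.labels):
            raise ValueError("rows and labels must align")
        n = len(self.values)
        if self.patient_ids is None:
            self.patient_ids = np.array([""] * n, dtype=object)
        else:
            self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        if self.window_index is None:
            self.window_index = np.arange(n)
        else:
            self.window_index = np.asarray(self.window_index, dtype=int)
        if len(self.patient_ids) != n or len(self.window_index) != n:
            raise ValueError("metadata columns must align with rows")

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.loc[:, list(names)].copy(),
            self.labels.copy(),
            self.patient_ids.copy(),
            self.window_index.copy(),
        )

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            self.patient_ids[idx],
            self.window_index[idx],
        )


# ---------------------------------------------------------------------------
# Signal primitives


def magnitude_signal(series: TriAxialSeries) -> np.ndarray:
    """Per-sample vector magnitude sqrt(x^2 + y^2 + z^2)."""
    return np.sqrt(series.x**2 + series.y**2 + series.z**2)


def sliding_windows(signal: Sequence[float] | np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Non-padded sliding windows starting at 0, step, 2*step, ...

    Returns an ``(n_windows, length)`` array; a signal shorter than one
    window yields an empty ``(0, length)`` array.  Trailing samples that do
    not fill a window are discarded.
    """
    sig = np.asarray(signal, dtype=float)
    n, L, step = len(sig), spec.length_samples, spec.step_samples
    if n < L:
        return np.empty((0, L))
    count = (n - L) // step + 1
    starts = np.arange(count) * step
    return np.stack([sig[s : s + L] for s in starts])


# ---------------------------------------------------------------------------
# Feature families


def statistical_features(window: Sequence[float] | np.ndarray) -> dict[str, float]:
    """Distributional summary of one window (12 values).

    Skewness and kurtosis use population (biased) moments; kurtosis is
    reported as excess kurtosis.  A constant window yields 0 for both by
    sentinel, and the coefficient of variation falls back to 0 when
    |mean| < 1e-12.
    """
    v = np.asarray(window, dtype=float)
    if len(v) < 2:
        raise ValueError("statistical features need at least 2 samples")
    q1, q3 = np.percentile(v, [25, 75])
    std = float(np.std(v))
    mean = float(np.mean(v))
    constant = std == 0.0
    return {
        "mean": mean,
        "median": float(np.median(v)),
        "std": std,
        "variance": float(np.var(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "range": float(np.max(v) - np.min(v)),
        "iqr": float(q3 - q1),
        "quartile_deviation": float((q3 - q1) / 2.0),
        "skewness": 0.0 if constant else float(sps.skew(v, bias=True)),
        "kurtosis": 0.0 if constant else float(sps.kurtosis(v, fisher=True, bias=True)),
        "coefficient_of_variation": 0.0 if abs(mean) < _CV_SENTINEL_EPS else std / abs(mean),
    }


def energy_features(window: Sequence[float] | np.ndarray) -> dict[str, float]:
    """Intensity measures: SMA, RMS, total energy and log energy."""
    v = np.asarray(window, dtype=float)
    if len(v) < 1:
        raise ValueError("energy features need at least 1 sample")
    return {
        "sma": float(np.mean(np.abs(v))),
        "rms": float(np.sqrt(np.mean(v**2))),
        "total_energy": float(np.sum(v**2)),
        "log_energy": float(np.sum(np.log(v**2 + _LOG_ENERGY_EPS))),
    }


def _power_spectrum(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean-removed rectangular-window one-sided periodogram (freqs, power)."""
    v = window - np.mean(window)
    spec = np.fft.rfft(v)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(len(v), d=1.0 / fs)
    return freqs, power


def spectral_features(
    window: Sequence[float] | np.ndarray,
    fs: float,
    prev_spectrum: np.ndarray | None = None,
) -> dict[str, float]:
    """Frequency-domain summary of one window (8 values).

    All quantities come from the mean-removed one-sided power spectrum with a
    rectangular window.  The DC bin is excluded throughout (it is ~0 after
    mean removal anyway).  Spectral flux is the Euclidean distance to the
    previous window's power spectrum (0 for the first window); the roll-off
    is the lowest frequency below which at least 85% of the power lies.
    Entropy is Shannon entropy of the normalised power, itself normalised to
    [0, 1] by log of the bin count.  A zero-power (constant) window returns
    0 for every value.
    """
    v = np.asarray(window, dtype=float)
    if len(v) < 4:
        raise ValueError("spectral features need at least 4 samples")
    freqs, power = _power_spectrum(v, fs)
    f, p = freqs[1:], power[1:]  # drop DC
    total = float(np.sum(p))
    flux = 0.0
    if prev_spectrum is not None:
        flux = float(np.linalg.norm(p - np.asarray(prev_spectrum, dtype=float)))
    if total <= 0.0:
        return {name: 0.0 for name in SPECTRAL_NAMES} | {"spectral_flux": flux}
    prob = p / total
    centroid = float(np.sum(f * prob))
    spread = float(np.sqrt(np.sum((f - centroid) ** 2 * prob)))
    # geometric mean over arithmetic mean; tiny floor keeps log finite
    flatness = float(np.exp(np.mean(np.log(p + 1e-30))) / np.mean(p + 1e-30))
    nz = prob[prob > 0]
    entropy = float(-np.sum(nz * np.log(nz)) / np.log(len(p))) if len(p) > 1 else 0.0
    rolloff = float(f[int(np.searchsorted(np.cumsum(prob), 0.85))])
    return {
        "dominant_frequency": float(f[int(np.argmax(p))]),
        "spectral_flatness": flatness,
        "spectral_flux": flux,
        "spectral_variability": float(np.std(p)),
        "spectral_entropy": entropy,
        "spectral_centroid": centroid,
        "spectral_spread": spread,
        "spectral_rolloff": rolloff,
    }


# -- nonlinear dynamics ------------------------------------------------------


def sample_entropy(window: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln( A / B ) with Chebyshev distance, no self-matches.

    ``B`` counts template pairs of length ``m`` within tolerance ``r``
    (default 0.2 * std of the window) and ``A`` the pairs still within
    tolerance at length ``m+1``.  Degenerate cases (no matches, or zero
    spread) return the sentinel 0.
    """
    v = np.asarray(window, dtype=float)
    n = len(v)
    if r is None:
        r = 0.2 * float(np.std(v))
    if r <= 0 or n <= m + 1:
        return 0.0

    def count_matches(length: int) -> int:
        n_templates = n - length + 1
        templ = np.lib.stride_tricks.sliding_window_view(v, length)
        count = 0
        for i in range(n_templates - 1):
            d = np.max(np.abs(templ[i + 1 :] - templ[i]), axis=1)
            count += int(np.sum(d <= r))
        return count

    b = count_matches(m)
    a = count_matches(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def higuchi_fd(window: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension via least-squares on log L(k) vs log(1/k).

    For each lag ``k`` the mean normalised curve length L(k) is averaged over
    the ``k`` phase-shifted subsampled curves; the FD is the slope of
    log L(k) against log(1/k).  A straight line gives FD ~= 1.  Degenerate
    (constant) input returns the sentinel 1.0.
    """
    v = np.asarray(window, dtype=float)
    n = len(v)
    k_max = min(k_max, max(2, n // 2))
    lengths = []
    ks = []
    for k in range(1, k_max + 1):
        lk = 0.0
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if len(idx) < 2:
                continue
            dist = float(np.sum(np.abs(np.diff(v[idx]))))
            norm = (n - 1) / (len(idx) - 1) / k if len(idx) > 1 else 0.0
            lk += dist * norm / k
        lk /= k
        if lk > 0:
            lengths.append(np.log(lk))
            ks.append(np.log(1.0 / k))
    if len(lengths) < 2:
        return 1.0
    slope = np.polyfit(ks, lengths, 1)[0]
    return float(slope)


def lyapunov_exponent(
    window: np.ndarray,
    emb_dim: int = 2,
    delay: int = 1,
    fit_steps: int = 10,
) -> float:
    """Largest Lyapunov exponent by Rosenstein's mean-divergence method.

    Delay-embeds the window (dimension 2, delay 1), finds each point's
    nearest neighbour outside a 1-sample temporal exclusion zone, tracks the
    log of the pairwise distance over the first ``fit_steps`` steps and
    returns the least-squares slope of the mean log-divergence curve.
    Windows too short to supply neighbours or divergence return 0.
    """
    v = np.asarray(window, dtype=float)
    n = len(v)
    m = n - (emb_dim - 1) * delay
    if m < fit_steps + 3:
        return 0.0
    emb = np.stack([v[i * delay : i * delay + m] for i in range(emb_dim)], axis=1)
    # pairwise distances with temporal exclusion
    diff = emb[:, None, :] - emb[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    idx = np.arange(m)
    excl = np.abs(idx[:, None] - idx[None, :]) <= 1
    dist[excl] = np.inf
    neighbor = np.argmin(dist, axis=1)
    if not np.isfinite(dist[idx, neighbor]).any():
        return 0.0
    mean_log = []
    for step in range(fit_steps + 1):
        valid = (idx + step < m) & (neighbor + step < m)
        if not np.any(valid):
            break
        d = np.linalg.norm(emb[idx[valid] + step] - emb[neighbor[valid] + step], axis=1)
        d = d[d > 0]
        if len(d) == 0:
            break
        mean_log.append(float(np.mean(np.log(d))))
    if len(mean_log) < 2:
        return 0.0
    steps = np.arange(len(mean_log))
    slope = np.polyfit(steps, mean_log, 1)[0]
    return float(slope)


def nonlinear_features(window: Sequence[float] | np.ndarray) -> dict[str, float]:
    """Dynamics and complexity measures of one window (5 values)."""
    v = np.asarray(window, dtype=float)
    if len(v) < 20:
        raise ValueError("nonlinear features need at least 20 samples")
    diffs = np.diff(v)
    return {
        "mad": float(np.mean(np.abs(v - np.mean(v)))),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "higuchi_fractal_dimension": higuchi_fd(v),
        "lyapunov_exponent": lyapunov_exponent(v),
        "sample_entropy": sample_entropy(v),
    }


def window_features(
    window: np.ndarray,
    fs: float,
    prev_spectrum: np.ndarray | None = None,
) -> tuple[dict[str, float], np.ndarray]:
    """All 29 features of one window; also returns the power spectrum so the
    caller can thread spectral flux between consecutive windows."""
    out: dict[str, float] = {}
    out.update(statistical_features(window))
    out.update(energy_features(window))
    out.update(spectral_features(window, fs, prev_spectrum))
    out.update(nonlinear_features(window))
    _, power = _power_spectrum(np.asarray(window, dtype=float), fs)
    return out, power[1:]


# ---------------------------------------------------------------------------
# Matrix assembly


def extract_feature_matrix(
    sessions: Sequence[RecordingSession],
    spec: WindowSpec | None = None,
) -> FeatureMatrix:
    """Windowed 87-column feature matrix for one exercise.

    Per session and sensor the magnitude signal is windowed and the 29-name
    bank computed, giving 29 x 3 sensor-prefixed columns ("acce_mean", ...).
    One row per window; labels come from the session state.  Sessions are
    processed in the given order and windows in time order, so row ordering
    is deterministic.  All sessions must share the exercise.
    """
    if spec is None:
        spec = WindowSpec()
    if not sessions:
        raise ValueError("no sessions given")
    exercises = {s.exercise for s in sessions}
    if len(exercises) != 1:
        raise ValueError(f"sessions mix exercises {sorted(exercises)}; one matrix per exercise")

    columns = [f"{sensor}_{name}" for sensor in SENSOR_NAMES for name in FEATURE_NAMES]
    rows: list[dict[str, float]] = []
    labels: list[int] = []
    patients: list[str] = []
    windex: list[int] = []
    for session in sessions:
        per_sensor_windows = {
            sensor: sliding_windows(magnitude_signal(session.sensors[sensor]), spec)
            for sensor in SENSOR_NAMES
        }
        n_windows = min(len(w) for w in per_sensor_windows.values())
        prev_spec: dict[str, np.ndarray | None] = {s: None for s in SENSOR_NAMES}
        for w in range(n_windows):
            row: dict[str, float] = {}
            for sensor in SENSOR_NAMES:
                feats, spectrum = window_features(
                    per_sensor_windows[sensor][w], session.fs, prev_spec[sensor]
                )
                prev_spec[sensor] = spectrum
                for name, value in feats.items():
                    row[f"{sensor}_{name}"] = value
            rows.append(row)
            labels.append(session.label)
            patients.append(session.patient_id)
            windex.append(w)

    values = pd.DataFrame(rows, columns=columns, dtype=float)
    bad = ~np.isfinite(values.to_numpy())
    if bad.any():
        warnings.warn(f"replaced {int(bad.sum())} non-finite feature values with 0")
        values = values.where(np.isfinite(values), 0.0)
    return FeatureMatrix(values, np.asarray(labels), np.asarray(patients, dtype=object), np.asarray(windex))
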