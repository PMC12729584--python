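"""Feature-bank unit tests against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gefc.signal_features import (
    FEATURE_NAMES,
    RecordingSession,
    TriAxialSeries,
    WindowSpec,
    energy_features,
    extract_feature_matrix,
    higuchi_fd,
    magnitude_signal,
    nonlinear_features,
    sample_entropy,
    sliding_windows,
    spectral_features,
    statistical_features,
)

# ---------------------------------------------------------------------------
# independent oracles


def sample_entropy_oracle(v, m=2, r=None):
    """Plain O(n^2) template counting from the definition."""
    v = np.asarray(v, float)
    n = len(v)
    if r is None:
        r = 0.2 * np.std(v)

    def count(length):
        c = 0
        for i in range(n - length + 1):
            for j in range(i + 1, n - length + 1):
                if max(abs(v[i + k] - v[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return -np.log(a / b)


def higuchi_oracle(v, k_max=10):
    """Direct loop implementation of the curve-length slope estimate."""
    v = np.asarray(v, float)
    n = len(v)
    k_max = min(k_max, max(2, n // 2))
    xs, ys = [], []
    for k in range(1, k_max + 1):
        total = 0.0
        for m0 in range(k):
            idx = list(range(m0, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(v[idx[i + 1]] - v[idx[i]]) for i in range(len(idx) - 1))
            total += dist * (n - 1) / ((len(idx) - 1) * k) / k
        lk = total / k
        if lk > 0:
            xs.append(np.log(1.0 / k))
            ys.append(np.log(lk))
    return float(np.polyfit(xs, ys, 1)[0])


# ---------------------------------------------------------------------------
# magnitude


def test_magnitude_345_triangle():
    s = TriAxialSeries(np.full(5, 3.0), np.full(5, 4.0), np.zeros(5))
    assert np.allclose(magnitude_signal(s), 5.0)


def test_magnitude_zero_series():
    s = TriAxialSeries(np.zeros(4), np.zeros(4), np.zeros(4))
    assert np.allclose(magnitude_signal(s), 0.0)


def test_magnitude_matches_elementwise_oracle(rng):
    x, y, z = rng.normal(size=(3, 10))
    got = magnitude_signal(TriAxialSeries(x, y, z))
    expected = [np.sqrt(xi**2 + yi**2 + zi**2) for xi, yi, zi in zip(x, y, z)]
    assert np.allclose(got, expected, atol=1e-12)
    assert np.all(got >= 0)


def test_empty_series_rejected():
    with pytest.raises(ValueError):
        TriAxialSeries(np.array([]), np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# windowing


@pytest.mark.parametrize(
    "n,length,step,expected",
    [(100, 100, 50, 1), (250, 100, 50, 4), (99, 100, 50, 0), (1000, 100, 50, 19)],
)
def test_window_counts(n, length, step, expected):
    w = sliding_windows(np.arange(n, dtype=float), WindowSpec(length, step))
    assert len(w) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n=st.integers(0, 400),
    length=st.integers(1, 120),
    step_frac=st.integers(1, 120),
)
def test_window_count_formula_property(n, length, step_frac):
    """Count and start offsets match brute-force enumeration of starts."""
    step = min(step_frac, length)
    w = sliding_windows(np.arange(n, dtype=float), WindowSpec(length, step))
    starts = [s for s in range(0, max(n - length + 1, 0), step)] if n >= length else []
    # brute force: every start position s with s+length <= n and s multiple of step
    brute = [s for s in range(0, n) if s % step == 0 and s + length <= n]
    assert len(w) == len(brute)
    for win, s in zip(w, brute):
        assert win[0] == s and win[-1] == s + length - 1


# ---------------------------------------------------------------------------
# statistical / energy


def test_statistical_constant_window_sentinels():
    f = statistical_features(np.full(30, 2.5))
    for key in ("std", "variance", "range", "iqr", "quartile_deviation",
                "skewness", "kurtosis"):
        assert f[key] == 0.0
    assert f["mean"] == 2.5


def test_statistical_symmetric_window_zero_skew():
    v = np.concatenate([np.arange(-5, 6), -np.arange(-5, 6)])
    assert abs(statistical_features(v)["skewness"]) < 1e-12


def test_statistical_mean_oracle():
    v = np.arange(1, 101, dtype=float)
    f = statistical_features(v)
    assert f["mean"] == pytest.approx(sum(v) / len(v), abs=1e-12)
    assert f["median"] == pytest.approx(50.5)
    assert f["range"] == 99.0


def test_statistical_rejects_tiny_window():
    with pytest.raises(ValueError):
        statistical_features([1.0])


def test_energy_closed_forms():
    assert energy_features(np.zeros(10)) == pytest.approx(
        {"sma": 0.0, "rms": 0.0, "total_energy": 0.0,
         "log_energy": 10 * np.log(1e-12)}, abs=1e-9
    )
    f = energy_features(np.full(100, 2.0))
    assert f["rms"] == pytest.approx(2.0)
    assert f["total_energy"] == pytest.approx(400.0)


def test_energy_sine_rms_analytic_limit():
    t = np.arange(1000) / 100.0
    v = 3.0 * np.sin(2 * np.pi * 5 * t)  # whole periods
    assert energy_features(v)["rms"] == pytest.approx(3.0 / np.sqrt(2), rel=1e-6)


# ---------------------------------------------------------------------------
# spectral


def test_spectral_pure_tone():
    t = np.arange(100) / 100.0
    f = spectral_features(np.sin(2 * np.pi * 5 * t), fs=100.0)
    assert f["dominant_frequency"] == pytest.approx(5.0)
    assert f["spectral_spread"] == pytest.approx(0.0, abs=1e-6)
    assert f["spectral_rolloff"] == pytest.approx(5.0)


def test_spectral_flat_spectrum(rng):
    # synthesise equal power in all non-DC bins with random phases
    n = 128
    phases = rng.uniform(0, 2 * np.pi, n // 2 + 1)
    spec = np.exp(1j * phases)
    spec[0] = 0.0
    spec[-1] = 1.0  # Nyquist bin must be real to keep unit magnitude after irfft
    v = np.fft.irfft(spec, n)
    f = spectral_features(v, fs=100.0)
    assert f["spectral_flatness"] == pytest.approx(1.0, abs=1e-6)
    assert f["spectral_entropy"] == pytest.approx(1.0, abs=1e-6)


def test_spectral_flux_identical_windows(rng):
    v = rng.normal(size=100)
    first = spectral_features(v, 100.0, prev_spectrum=None)
    assert first["spectral_flux"] == 0.0
    from gefc.signal_features import _power_spectrum

    _, power = _power_spectrum(v, 100.0)
    again = spectral_features(v, 100.0, prev_spectrum=power[1:])
    assert again["spectral_flux"] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# nonlinear


def test_nonlinear_constant_window():
    f = nonlinear_features(np.full(30, 1.0))
    assert f["mad"] == 0.0 and f["rmssd"] == 0.0
    assert f["sample_entropy"] == 0.0  # zero tolerance sentinel


def test_rmssd_alternating():
    v = np.tile([1.0, -1.0], 15)
    assert nonlinear_features(v)["rmssd"] == pytest.approx(2.0)


def test_sample_entropy_matches_bruteforce(rng):
    for _ in range(5):
        v = rng.normal(size=30)
        assert sample_entropy(v) == pytest.approx(sample_entropy_oracle(v), abs=1e-9)


def test_higuchi_matches_bruteforce(rng):
    for _ in range(5):
        v = rng.normal(size=50)
        assert higuchi_fd(v) == pytest.approx(higuchi_oracle(v), abs=1e-9)


def test_higuchi_straight_line_near_one():
    assert higuchi_fd(np.linspace(0, 1, 100)) == pytest.approx(1.0, abs=0.05)


def test_nonlinear_rejects_short_window():
    with pytest.raises(ValueError):
        nonlinear_features(np.ones(10))


# ---------------------------------------------------------------------------
# shift behaviour and finiteness


def test_feature_shift_behaviour(rng):
    v = rng.normal(size=100)
    c = 7.3
    base_s, shift_s = statistical_features(v), statistical_features(v + c)
    assert shift_s["mean"] == pytest.approx(base_s["mean"] + c, abs=1e-9)
    for inv in ("std", "iqr", "variance", "range"):
        assert shift_s[inv] == pytest.approx(base_s[inv], abs=1e-9)
    base_n, shift_n = nonlinear_features(v), nonlinear_features(v + c)
    assert shift_n["rmssd"] == pytest.approx(base_n["rmssd"], abs=1e-9)
    assert shift_n["mad"] == pytest.approx(base_n["mad"], abs=1e-9)


def test_all_features_finite_on_random_windows(rng):
    from gefc.signal_features import window_features

    for scale in (1e-6, 1.0, 1e4):
        v = rng.normal(scale=scale, size=100)
        feats, _ = window_features(v, fs=100.0)
        assert set(feats) == set(FEATURE_NAMES)
        assert all(np.isfinite(val) for val in feats.values())


# ---------------------------------------------------------------------------
# matrix assembly


def _mk_session(n=250, exercise=0, state="OFF", patient="P1", seed=0):
    r = np.random.default_rng(seed)
    sensors = {
        name: TriAxialSeries(*r.normal(size=(3, n)), fs=100.0)
        for name in ("acce", "gyro", "magn")
    }
    return RecordingSession(patient, exercise, state, sensors)


def test_extract_rows_columns_labels():
    m = extract_feature_matrix([_mk_session(250)])
    assert len(m) == 4  # floor((250-100)/50)+1
    assert len(m.column_names) == 87  # 29 features x 3 sensors
    assert set(m.labels) == {0}
    assert m.column_names[0].startswith("acce_")


def test_extract_rejects_mixed_exercises():
    with pytest.raises(ValueError):
        extract_feature_matrix([_mk_session(exercise=0), _mk_session(exercise=1)])


def test_extract_deterministic_ordering():
    sessions = [_mk_session(seed=1), _mk_session(state="ON", seed=2)]
    a = extract_feature_matrix(sessions)
    b = extract_feature_matrix(sessions)
    assert a.values.equals(b.values)
    assert np.array_equal(a.labels, b.labels)
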