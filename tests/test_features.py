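"""Feature formulas against independent brute-force oracles."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from wristhar.features import (
    CATALOG,
    N_FEATURES,
    correlation,
    dc_component,
    energy,
    extract_features,
    feature_frame,
    kurtosis,
    skewness,
    spectral_entropy,
    spectrum,
    window_energy,
    zero_crossing_rate,
)
from wristhar.windows import Window


# --- independent oracles: plain-Python direct summation -------------------

def naive_mean(v):
    return sum(v) / len(v)


def naive_std(v):
    m = naive_mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))


def naive_skew(v):
    n, m, s = len(v), naive_mean(v), naive_std(v)
    return n / ((n - 1) * (n - 2)) * sum((x - m) ** 3 for x in v) / s ** 3


def naive_kurt(v):
    n, m, s = len(v), naive_mean(v), naive_std(v)
    a = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * sum((x - m) ** 4 for x in v) / s ** 4
    return a - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))


def naive_corr(u, v):
    mu, mv = naive_mean(u), naive_mean(v)
    cov = sum((a - mu) * (b - mv) for a, b in zip(u, v)) / (len(u) - 1)
    return cov / (naive_std(u) * naive_std(v))


def naive_dft(v):
    n = len(v)
    return [sum(v[k] * np.exp(-2j * np.pi * i * k / n) for k in range(n))
            for i in range(n)]


# --- moments ---------------------------------------------------------------

@pytest.mark.parametrize("v, expected", [
    ([1, 2, 3], 0.0),
    ([1, 2, 2, 3], 0.0),
    ([1, 1, 1, 5], 2.0),          # hand evaluation of the corrected formula
])
def test_skewness_examples(v, expected):
    assert skewness(np.array(v, float)) == pytest.approx(expected, abs=1e-12)


def test_kurtosis_hand_example():
    # sum of 4th-power deviations = 34, sample variance = 2.5
    assert kurtosis(np.array([1, 2, 3, 4, 5], float)) == pytest.approx(-1.2)


def test_moments_affine_invariance(rng):
    v = rng.normal(size=50)
    for a, b in [(2.5, -3.0), (0.1, 100.0)]:
        assert skewness(a * v + b) == pytest.approx(skewness(v), abs=1e-9)
        assert kurtosis(a * v + b) == pytest.approx(kurtosis(v), abs=1e-9)


def test_constant_vector_conventions():
    c = np.full(10, 3.3)
    assert skewness(c) == 0.0
    assert kurtosis(c) == 0.0
    assert correlation(c, np.arange(10.0)) == 0.0
    assert zero_crossing_rate(c) == 0.0


def test_moments_match_scipy(rng):
    """Cross-check the bias-corrected forms against an independent library."""
    for _ in range(10):
        v = rng.normal(size=40)
        assert skewness(v) == pytest.approx(scipy.stats.skew(v, bias=False), rel=1e-12)
        assert kurtosis(v) == pytest.approx(
            scipy.stats.kurtosis(v, bias=False, fisher=True), rel=1e-12)


# --- correlation and zero crossings ---------------------------------------

def test_correlation_examples():
    x = np.array([1.0, 2.0, 3.0])
    assert correlation(x, x) == pytest.approx(1.0)
    assert correlation(x, -x) == pytest.approx(-1.0)
    y = np.array([1.0, 2.0, 4.0])
    assert correlation(x, y) == pytest.approx(naive_corr(x, y), rel=1e-12)


@pytest.mark.parametrize("v, expected", [
    ([1.0, 1.0, 2.0], 0.0),
    ([1.0, -1.0, 1.0, -1.0], 1.0),
    ([1.0, 0.0, -1.0], 0.5),       # zero carries the previous nonzero sign
    ([0.0, 0.0, 1.0], 0.0),        # leading zeros carry no sign
    ([1.0, 0.0, 1.0], 0.0),
])
def test_zero_crossing_rate(v, expected):
    assert zero_crossing_rate(np.array(v)) == pytest.approx(expected)


# --- spectral features ------------------------------------------------------

def test_spectrum_closed_forms(rng):
    c = 2.5
    s = spectrum(np.full(4, c))
    assert s[0] == pytest.approx(4 * c)
    assert np.allclose(s[1:], 0.0, atol=1e-12)
    assert np.allclose(spectrum(np.zeros(8)), 0.0)
    v = rng.normal(size=8)
    np.testing.assert_allclose(spectrum(v), naive_dft(v), atol=1e-9)


def test_dc_component(rng):
    assert dc_component(spectrum(np.full(16, -1.5))) == pytest.approx(1.5)
    assert dc_component(spectrum(np.zeros(16))) == 0.0
    v = rng.normal(size=8)
    assert dc_component(spectrum(v)) == pytest.approx(abs(naive_mean(v)), rel=1e-12)


def test_spectral_entropy_cases():
    # single nonzero non-DC bin: degenerate distribution
    s = np.zeros(8, complex)
    s[3] = 5.0
    assert spectral_entropy(s) == 0.0
    # all non-DC bins equal: uniform over N-1 bins
    s = np.ones(9, complex)
    assert spectral_entropy(s) == pytest.approx(math.log2(8))
    # two equal bins
    s = np.zeros(8, complex)
    s[2] = s[5] = 1.0
    assert spectral_entropy(s) == pytest.approx(1.0)
    assert spectral_entropy(np.zeros(4, complex)) == 0.0


def test_energy(rng):
    assert energy(spectrum(np.zeros(16))) == 0.0
    c = 0.7
    assert energy(spectrum(np.full(16, c))) == pytest.approx(c)
    v = rng.normal(size=16)
    brute = naive_mean([abs(x) for x in naive_dft(v)])
    assert energy(spectrum(v)) == pytest.approx(brute, rel=1e-9)


# --- full vector ------------------------------------------------------------

def test_catalog_is_105_unique_names():
    assert len(CATALOG) == N_FEATURES == 105
    assert len(set(CATALOG.names)) == 105


def random_window(rng, n=120):
    return Window(start=0, data=rng.normal(size=(n, 9)))


def test_extract_matches_oracles(rng):
    """Every moment/correlation feature agrees with direct summation to 1e-9."""
    w = random_window(rng)
    fv = extract_features(w)
    from wristhar.codec import AXIS_NAMES
    for i, axis in enumerate(AXIS_NAMES):
        v = list(w.data[:, i])
        assert fv[CATALOG.index(f"{axis}_mean")] == pytest.approx(naive_mean(v), rel=1e-9)
        assert fv[CATALOG.index(f"{axis}_std")] == pytest.approx(naive_std(v), rel=1e-9)
        assert fv[CATALOG.index(f"{axis}_skew")] == pytest.approx(naive_skew(v), rel=1e-9)
        assert fv[CATALOG.index(f"{axis}_kurt")] == pytest.approx(naive_kurt(v), rel=1e-9)
    for a, b in [("ax", "ay"), ("ax", "mz"), ("gy", "gz")]:
        u = w.data[:, AXIS_NAMES.index(a)]
        v = w.data[:, AXIS_NAMES.index(b)]
        assert fv[CATALOG.index(f"corr_{a}_{b}")] == pytest.approx(
            naive_corr(list(u), list(v)), rel=1e-9)
    # sensor averages are unweighted means of the per-axis values
    accel_means = [fv[CATALOG.index(f"{a}_mean")] for a in ("ax", "ay", "az")]
    assert fv[CATALOG.index("accel_mean_avg")] == pytest.approx(naive_mean(accel_means))


def test_extract_is_pure_and_zero_safe(rng):
    w = random_window(rng)
    a = extract_features(w)
    b = extract_features(Window(start=0, data=w.data.copy()))
    np.testing.assert_array_equal(a, b)  # bit-identical on identical windows
    z = extract_features(Window(start=0, data=np.zeros((120, 9))))
    np.testing.assert_array_equal(z, np.zeros(105))


def test_window_energy_is_mean_of_accel_energies(rng):
    w = random_window(rng)
    fv = extract_features(w)
    expected = np.mean([fv[CATALOG.index(f"{a}_energy")] for a in ("ax", "ay", "az")])
    assert window_energy(fv) == pytest.approx(expected)


def test_feature_frame_layout(rng):
    wins = [Window(start=i, data=rng.normal(size=(120, 9)), label="walking")
            for i in range(3)]
    df = feature_frame(wins)
    assert list(df.columns) == list(CATALOG.names) + ["label"]
    assert (df["label"] == "walking").all()
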