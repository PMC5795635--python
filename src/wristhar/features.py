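"""Per-window feature extraction: the 105-dimensional catalog.

Each window yields, in a fixed documented order:

* per axis (9 axes x 5 statistics = 45): mean, sample standard deviation,
  bias-corrected skewness, bias-corrected excess kurtosis, zero-crossing
  rate;
* per sensor (3 sensors x 5 = 15): the unweighted average of each of those
  five statistics over the sensor's three axes;
* Pearson correlation for all C(9,2) = 36 unordered axis pairs;
* per acceleration axis (3 x 3 = 9): DC component, spectral entropy and
  spectral energy, derived from the unnormalized FFT of the axis.

Total: 45 + 15 + 36 + 9 = 105 named features.

Conventions for degenerate inputs are frozen here: a constant axis
(sigma = 0) has skewness, kurtosis and any correlation involving it set
to 0; spectral entropy of an all-zero spectrum is 0.  Zero samples carry
the previous nonzero sign when counting zero crossings.  Spectral energy
is the mean of the FFT coefficient magnitudes over all bins, DC included;
spectral entropy is computed over the non-DC bins only, so it reflects
spectral shape rather than offset.

The statistics use the bias-corrected (sample, N-1) forms:

    skew(W) = N / ((N-1)(N-2)) * sum((w_i - mean)^3) / sigma^3
    kurt(W) = N(N+1) / ((N-1)(N-2)(N-3)) * sum((w_i - mean)^4) / sigma^4
              - 3(N-1)^2 / ((N-2)(N-3))
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from wristhar.codec import AXIS_NAMES
from wristhar.windows import Window

logger = logging.getLogger(__name__)

SENSORS = {"accel": ("ax", "ay", "az"),
           "gyro": ("gx", "gy", "gz"),
           "mag": ("mx", "my", "mz")}
AXIS_STATS = ("mean", "std", "skew", "kurt", "zcr")
ACCEL_AXES = ("ax", "ay", "az")
SPECTRAL_STATS = ("dc", "spectral_entropy", "energy")

N_FEATURES = 105


def skewness(v: np.ndarray) -> float:
    """Bias-corrected sample skewness; 0 for a constant vector."""
    v = np.asarray(v, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("skewness requires N >= 3")
    d = v - v.mean()
    s = v.std(ddof=1)
    if s == 0:
        return 0.0
    return n / ((n - 1) * (n - 2)) * float(np.sum(d ** 3)) / s ** 3


def kurtosis(v: np.ndarray) -> float:
    """Bias-corrected excess kurtosis; 0 for a constant vector."""
    v = np.asarray(v, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError("kurtosis requires N >= 4")
    d = v - v.mean()
    s = v.std(ddof=1)
    if s == 0:
        return 0.0
    term = n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float(np.sum(d ** 4)) / s ** 4
    return term - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))


def correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation cov(U,V)/(sigma_u sigma_v); 0 when either is constant."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size:
        raise ValueError("correlation requires equal lengths")
    su, sv = u.std(ddof=1), v.std(ddof=1)
    if su == 0 or sv == 0:
        logger.debug("constant axis in correlation; returning 0")
        return 0.0
    cov = float(np.sum((u - u.mean()) * (v - v.mean()))) / (u.size - 1)
    return cov / (su * sv)


def zero_crossing_rate(v: np.ndarray) -> float:
    """Fraction of consecutive pairs with strictly opposite sign.

    Zero samples inherit the previous nonzero sign, so a touch of the axis
    without a sign change is not a crossing.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("zero-crossing rate requires N >= 2")
    signs = np.sign(v)
    last = 0.0
    for i in range(signs.size):  # carry previous nonzero sign through zeros
        if signs[i] == 0.0:
            signs[i] = last
        else:
            last = signs[i]
    return float(np.count_nonzero(signs[:-1] * signs[1:] < 0)) / (v.size - 1)


def spectrum(v: np.ndarray) -> np.ndarray:
    """Unnormalized DFT of the axis (coefficient 0 is the DC term)."""
    return np.fft.fft(np.asarray(v, dtype=float))


def dc_component(s: np.ndarray) -> float:
    """Mean level of the axis: |X_0| / N."""
    return float(np.abs(s[0])) / s.size


def spectral_entropy(s: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized power over non-DC bins."""
    power = np.abs(s[1:]) ** 2
    total = power.sum()
    if total == 0:
        return 0.0
    p = power / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def energy(s: np.ndarray) -> float:
    """Mean magnitude of the FFT coefficients, all bins included."""
    return float(np.mean(np.abs(s)))


@dataclass(frozen=True)
class FeatureCatalog:
    """Deterministic name -> index catalog of the feature vector."""

    names: tuple[str, ...]

    @classmethod
    def default(cls) -> "FeatureCatalog":
        names: list[str] = []
        for axis in AXIS_NAMES:
            names += [f"{axis}_{stat}" for stat in AXIS_STATS]
        for sensor in SENSORS:
            names += [f"{sensor}_{stat}_avg" for stat in AXIS_STATS]
        for a, b in itertools.combinations(AXIS_NAMES, 2):
            names.append(f"corr_{a}_{b}")
        for axis in ACCEL_AXES:
            names += [f"{axis}_{stat}" for stat in SPECTRAL_STATS]
        return cls(tuple(names))

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_json(self) -> str:
        return json.dumps({"version": 1, "names": list(self.names)})


CATALOG = FeatureCatalog.default()
assert len(CATALOG) == N_FEATURES

ENERGY_FEATURES = tuple(f"{axis}_energy" for axis in ACCEL_AXES)


def extract_features(w: Window, catalog: FeatureCatalog = CATALOG) -> np.ndarray:
    """Compute the full feature vector of one window, in catalog order."""
    if w.data.shape[1] != len(AXIS_NAMES):
        raise ValueError("window must carry all 9 axes")
    axes = {name: w.axis(name) for name in AXIS_NAMES}

    per_axis: dict[str, dict[str, float]] = {}
    for name, v in axes.items():
        per_axis[name] = {
            "mean": float(v.mean()),
            "std": float(v.std(ddof=1)),
            "skew": skewness(v),
            "kurt": kurtosis(v),
            "zcr": zero_crossing_rate(v),
        }

    values: dict[str, float] = {}
    for axis, stats in per_axis.items():
        for stat, val in stats.items():
            values[f"{axis}_{stat}"] = val
    for sensor, members in SENSORS.items():
        for stat in AXIS_STATS:
            values[f"{sensor}_{stat}_avg"] = float(
                np.mean([per_axis[m][stat] for m in members])
            )
    for a, b in itertools.combinations(AXIS_NAMES, 2):
        values[f"corr_{a}_{b}"] = correlation(axes[a], axes[b])
    for axis in ACCEL_AXES:
        s = spectrum(axes[axis])
        values[f"{axis}_dc"] = dc_component(s)
        values[f"{axis}_spectral_entropy"] = spectral_entropy(s)
        values[f"{axis}_energy"] = energy(s)

    return np.array([values[n] for n in catalog.names], dtype=float)


def window_energy(fv: np.ndarray, catalog: FeatureCatalog = CATALOG) -> float:
    """Scalar energy of a window: mean of the three per-axis energy features."""
    idx = [catalog.index(n) for n in ENERGY_FEATURES]
    return float(np.mean(fv[idx]))


def feature_frame(windows: Sequence[Window],
                  catalog: FeatureCatalog = CATALOG) -> pd.DataFrame:
    """Feature matrix with catalog-named columns plus a label column."""
    rows = [extract_features(w, catalog) for w in windows]
    df = pd.DataFrame(rows, columns=list(catalog.names))
    df["label"] = [w.label for w in windows]
    return df
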