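"""Sliding-window segmentation of 9-axis sample streams.

Recognition runs on fixed-duration windows with 50% overlap at the nominal
60 Hz rate: 2 s windows (120 samples) for daily activities and 6 s windows
(360 samples) for rehabilitation exercises.  Windows are defined by sample
count, not wall time, so features are deterministic even with timestamp
jitter; a gap detector restarts the buffer when the inter-sample interval
exceeds twice the nominal period.  Trailing partial windows are dropped
rather than padded, since padding would distort moments and spectra.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from wristhar.codec import AXIS_NAMES, NOMINAL_RATE_HZ, ImuSample

logger = logging.getLogger(__name__)

DAILY_WINDOW_S = 2.0
EXERCISE_WINDOW_S = 6.0


@dataclass(frozen=True)
class WindowConfig:
    """Window duration (s), overlap fraction and nominal sampling rate."""

    duration: float
    overlap: float = 0.5
    rate: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        length = self.duration * self.rate
        if abs(length - round(length)) > 1e-9 or round(length) < 1:
            raise ValueError(f"window length {length} is not a positive integer")
        step = round(length) * (1.0 - self.overlap)
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(f"window step {step} is not a positive integer")

    @property
    def length(self) -> int:
        return round(self.duration * self.rate)

    @property
    def step(self) -> int:
        return round(self.length * (1.0 - self.overlap))


DAILY_CONFIG = WindowConfig(DAILY_WINDOW_S)
EXERCISE_CONFIG = WindowConfig(EXERCISE_WINDOW_S)


@dataclass(frozen=True)
class Window:
    """A fixed-length contiguous block of samples.

    ``data`` has shape (L, 9), columns ordered as
    ax, ay, az, gx, gy, gz, mx, my, mz.
    """

    start: int
    data: np.ndarray
    t0: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(AXIS_NAMES):
            raise ValueError(
                f"window data must be (L, {len(AXIS_NAMES)}), got {self.data.shape}"
            )

    @property
    def length(self) -> int:
        return self.data.shape[0]

    def axis(self, name: str) -> np.ndarray:
        return self.data[:, AXIS_NAMES.index(name)]

    def to_json(self) -> str:
        return json.dumps(
            {"start": self.start, "t0": self.t0, "label": self.label,
             "data": self.data.tolist()}
        )


def _as_matrix(stream) -> np.ndarray:
    if isinstance(stream, pd.DataFrame):
        return stream[list(AXIS_NAMES)].to_numpy(dtype=float)
    if len(stream) and isinstance(stream[0], ImuSample):
        return np.array([s.axes() for s in stream], dtype=float)
    return np.asarray(stream, dtype=float)


def segment(stream, cfg: WindowConfig, labels: Sequence[str] | None = None) -> list[Window]:
    """Cut a time-sorted stream into overlapping fixed-length windows.

    ``stream`` may be a DataFrame with the standard axis columns, a sequence
    of :class:`ImuSample`, or an (N, 9) array.  Window *i* covers samples
    ``[i*step, i*step + L)``; the trailing partial window is dropped.  When
    per-sample ``labels`` are given, each window is labelled by the strict
    majority label of its samples and dropped if no label holds a majority.
    """
    mat = _as_matrix(stream)
    n = mat.shape[0]
    L, step = cfg.length, cfg.step
    if n < L:
        return []
    t = (stream["t"].to_numpy(dtype=float)
         if isinstance(stream, pd.DataFrame) and "t" in stream.columns
         else np.arange(n) / cfg.rate)
    out = []
    for i in range((n - L) // step + 1):
        s = i * step
        label = None
        if labels is not None:
            label = _majority_label(labels[s:s + L])
            if label is None:
                continue
        out.append(Window(start=s, data=mat[s:s + L], t0=float(t[s]), label=label))
    return out


def _majority_label(chunk: Sequence[str]) -> str | None:
    """Strict-majority label of a chunk, or None when no label covers > 1/2."""
    vals, counts = np.unique(np.asarray(chunk), return_counts=True)
    best = counts.argmax()
    if counts[best] * 2 > len(chunk):
        return str(vals[best])
    return None


class WindowAssembler:
    """Online counterpart of :func:`segment`.

    Feeding samples one by one emits exactly the windows the batch form
    would emit on the concatenated stream.  Out-of-order timestamps are
    rejected with a warning; a gap larger than twice the nominal period
    restarts the buffer (the stream is assumed regularly sampled).
    """

    def __init__(self, cfg: WindowConfig) -> None:
        self.cfg = cfg
        self._buf: list[ImuSample] = []
        self._start = 0          # stream index of buf[0]
        self._count = 0          # samples accepted so far
        self._last_t: float | None = None

    def reset(self) -> None:
        self._buf.clear()
        self._start = self._count

    def push(self, sample: ImuSample) -> Window | None:
        """Accept one sample; return a completed window when one closes."""
        if self._last_t is not None:
            dt = sample.t - self._last_t
            if dt <= 0:
                logger.warning("timestamp regression at t=%g; sample rejected", sample.t)
                return None
            if dt > 2.0 / self.cfg.rate:
                logger.warning("gap of %g s at t=%g; window buffer restarted", dt, sample.t)
                self.reset()
        self._last_t = sample.t
        self._buf.append(sample)
        self._count += 1
        L, step = self.cfg.length, self.cfg.step
        if len(self._buf) == L:
            w = Window(
                start=self._start,
                data=np.array([s.axes() for s in self._buf], dtype=float),
                t0=self._buf[0].t,
            )
            self._buf = self._buf[step:]
            self._start += step
            return w
        return None

    def feed(self, samples) -> Iterator[Window]:
        for s in samples:
            w = self.push(s)
            if w is not None:
                yield w


def dump_windows_jsonl(windows: Sequence[Window], path: str | Path) -> None:
    """Debug dump: one JSON object per window."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(w.to_json() + "\n")
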