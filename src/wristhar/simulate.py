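"""Synthetic 9-axis IMU streams with ground-truth labels.

No human dataset accompanies the recognizer, so this module generates
labelled streams with the statistical structure the pipeline assumes: each
activity class is a per-axis signature of a constant offset (the gravity
projection and magnetic-field baseline), a small set of sinusoidal
components (the quasi-periodic limb movement) and additive Gaussian noise.
These are deliberately abstract signatures, not biomechanical models: they
exercise the computation — codec, windowing, features, classifiers,
controller — under controlled separability, and say nothing about how well
the system recognizes real human movement.

The default session script mirrors a supervised collection protocol for
wrist-worn monitoring: five daily activities (walking and running recorded
for 30 s; sitting down and standing up repeated ten times; staying seated
30 s), a dedicated switch gesture, and four rehabilitation exercises
(front step down, squat on chair, front lunge, sit to stand), each
repeated ten times with repetitions performed back to back.  A cohort
applies per-subject amplitude and frequency jitter so that
leave-one-subject-out evaluation is meaningful; jitter 0 makes subjects
identical up to noise realization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from wristhar.codec import (
    ACCEL_FULL_SCALE,
    AXIS_NAMES,
    GYRO_FULL_SCALE,
    MAG_FULL_SCALE,
    NOMINAL_RATE_HZ,
)

_FULL_SCALE = {**{a: ACCEL_FULL_SCALE for a in ("ax", "ay", "az")},
               **{a: GYRO_FULL_SCALE for a in ("gx", "gy", "gz")},
               **{a: MAG_FULL_SCALE for a in ("mx", "my", "mz")}}
# Margin keeps every generated value strictly inside the open full-scale
# interval, so the codec never clamps simulator output.
_MARGIN = {**{a: 1e-3 for a in ("ax", "ay", "az", "mx", "my", "mz")},
           **{a: 1e-1 for a in ("gx", "gy", "gz")}}

DAILY_CLASSES = ("walking", "running", "sitting_down", "standing_up", "seated")
EXERCISE_CLASSES = ("front_step_down", "squat_chair", "front_lunge", "sit_to_stand")
SWITCH_CLASS = "switch"
ALL_CLASSES = DAILY_CLASSES + (SWITCH_CLASS,) + EXERCISE_CLASSES


@dataclass(frozen=True)
class ActivitySignature:
    """Sinusoid-plus-noise signature of one activity class.

    ``offsets`` maps axis name to a constant baseline; ``components`` maps
    axis name to (frequency Hz, amplitude) sinusoids; ``noise`` maps axis
    name to a Gaussian sigma.  ``rep_duration`` (s) is the length of one
    repetition for repetition-based classes; continuous classes set it to
    None and are generated for a requested duration.
    """

    label: str
    offsets: dict[str, float]
    components: dict[str, tuple[tuple[float, float], ...]]
    noise: dict[str, float]
    rep_duration: float | None = None

    def __post_init__(self) -> None:
        for axis, comps in self.components.items():
            for freq, amp in comps:
                if freq >= NOMINAL_RATE_HZ / 2:
                    raise ValueError(f"{self.label}/{axis}: {freq} Hz above Nyquist")
                reach = abs(self.offsets.get(axis, 0.0)) + sum(
                    a for _, a in self.components.get(axis, ())
                )
                if reach >= _FULL_SCALE[axis]:
                    raise ValueError(f"{self.label}/{axis}: amplitude exceeds full scale")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "offsets": self.offsets,
            "components": {a: [list(c) for c in cs] for a, cs in self.components.items()},
            "noise": self.noise,
            "rep_duration": self.rep_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActivitySignature":
        return cls(
            label=d["label"],
            offsets=dict(d["offsets"]),
            components={a: tuple(tuple(c) for c in cs)
                        for a, cs in d["components"].items()},
            noise=dict(d["noise"]),
            rep_duration=d.get("rep_duration"),
        )


def _sig(label, accel, gyro, rep=None, accel_noise=0.05, gyro_noise=4.0,
         mag_noise=0.02):
    """Compact signature builder.

    ``accel``/``gyro`` map axis -> (offset, ((freq, amp), ...)).  The
    magnetometer baseline is a fixed small field common to all classes.
    """
    offsets = {a: 0.0 for a in AXIS_NAMES}
    components: dict[str, tuple] = {a: () for a in AXIS_NAMES}
    for a, (off, comps) in accel.items():
        offsets[a] = off
        components[a] = tuple(comps)
    for a, (off, comps) in gyro.items():
        offsets[a] = off
        components[a] = tuple(comps)
    offsets.update({"mx": 0.25, "my": -0.1, "mz": 0.35})
    noise = {**{a: accel_noise for a in ("ax", "ay", "az")},
             **{a: gyro_noise for a in ("gx", "gy", "gz")},
             **{a: mag_noise for a in ("mx", "my", "mz")}}
    return ActivitySignature(label=label, offsets=offsets,
                             components=components, noise=noise,
                             rep_duration=rep)


def default_signatures() -> dict[str, ActivitySignature]:
    """Signature library for the ten classes of the default protocol.

    Running has higher RMS and dominant frequency than walking, which in
    turn exceeds the seated/postural classes; the four exercises are slow
    (one repetition every four seconds) but differ in axis mix and
    amplitude; the switch gesture is a fast, high-frequency wrist shake
    unlike anything else in the library.
    """
    return {s.label: s for s in [
        _sig("walking",
             accel={"ax": (0.95, ((1.8, 0.45),)), "ay": (0.1, ((1.8, 0.30),)),
                    "az": (0.05, ((3.6, 0.15),))},
             gyro={"gx": (0.0, ((1.8, 55.0),)), "gy": (0.0, ((1.8, 35.0),)),
                   "gz": (0.0, ((3.6, 18.0),))}),
        _sig("running",
             accel={"ax": (0.9, ((2.8, 1.45),)), "ay": (0.15, ((2.8, 0.95),)),
                    "az": (0.1, ((5.6, 0.55),))},
             gyro={"gx": (0.0, ((2.8, 260.0),)), "gy": (0.0, ((2.8, 150.0),)),
                   "gz": (0.0, ((5.6, 80.0),))},
             accel_noise=0.10, gyro_noise=8.0),
        _sig("sitting_down", rep=2.0,
             accel={"ax": (0.8, ((0.5, 0.35),)), "ay": (0.0, ((0.5, 0.20),)),
                    "az": (0.3, ((1.0, 0.10),))},
             gyro={"gx": (0.0, ((0.5, 45.0),)), "gy": (0.0, ((0.5, 20.0),))}),
        _sig("standing_up", rep=2.0,
             accel={"ax": (0.85, ((0.5, 0.25),)), "ay": (0.25, ((1.0, 0.25),)),
                    "az": (0.0, ((0.5, 0.18),))},
             gyro={"gy": (0.0, ((0.5, 55.0),)), "gz": (0.0, ((1.0, 25.0),))}),
        _sig("seated",
             accel={"ax": (0.7, ()), "ay": (0.35, ()), "az": (0.55, ())},
             gyro={}, accel_noise=0.02, gyro_noise=1.5),
        _sig(SWITCH_CLASS, rep=2.0,
             accel={"ax": (0.5, ((5.0, 0.85),)), "ay": (0.0, ((5.0, 0.85),)),
                    "az": (0.6, ((10.0, 0.30),))},
             gyro={"gx": (0.0, ((5.0, 320.0),)), "gy": (0.0, ((5.0, 300.0),))}),
        _sig("front_step_down", rep=4.0,
             accel={"ax": (0.9, ((0.25, 0.95),)), "ay": (0.05, ((0.5, 0.55),)),
                    "az": (0.2, ((0.25, 0.60),))},
             gyro={"gy": (0.0, ((0.25, 85.0),)), "gz": (0.0, ((0.5, 30.0),))}),
        _sig("squat_chair", rep=4.0,
             accel={"ax": (0.55, ((0.25, 1.25),)), "ay": (0.3, ((0.25, 0.65),)),
                    "az": (0.15, ((0.5, 0.45),))},
             gyro={"gx": (0.0, ((0.25, 130.0),)), "gy": (0.0, ((0.5, 45.0),))}),
        _sig("front_lunge", rep=4.0,
             accel={"ax": (0.75, ((0.25, 0.95), (0.75, 0.35))),
                    "ay": (-0.2, ((0.25, 0.80),)), "az": (0.1, ((0.75, 0.40),))},
             gyro={"gz": (0.0, ((0.25, 160.0),)), "gx": (0.0, ((0.75, 55.0),))}),
        _sig("sit_to_stand", rep=4.0,
             accel={"ax": (0.65, ((0.25, 0.75),)), "ay": (0.4, ((0.25, 0.60),)),
                    "az": (0.45, ((0.5, 0.70),))},
             gyro={"gy": (0.0, ((0.25, 60.0),)), "gx": (0.0, ((0.5, 35.0),))}),
    ]}


@dataclass(frozen=True)
class SessionScript:
    """Ordered (class, duration-or-repetitions) protocol for one recording.

    Entries are (label, {"duration": s}) or (label, {"reps": k}); reps are
    performed back to back, so a k-rep entry lasts k * rep_duration.
    """

    entries: tuple[tuple[str, dict], ...]
    subject: str = "s0"
    amp_jitter: float = 1.0   # multiplicative, applied to all amplitudes
    freq_jitter: float = 1.0  # multiplicative, applied to all frequencies


def default_protocol() -> tuple[tuple[str, dict], ...]:
    """The default collection protocol, one entry per class."""
    entries: list[tuple[str, dict]] = [
        ("walking", {"duration": 30.0}),
        ("running", {"duration": 30.0}),
        ("sitting_down", {"reps": 10}),
        ("standing_up", {"reps": 10}),
        ("seated", {"duration": 30.0}),
        (SWITCH_CLASS, {"reps": 10}),
    ]
    entries += [(c, {"reps": 10}) for c in EXERCISE_CLASSES]
    return tuple(entries)


def generate_activity(sig: ActivitySignature, duration: float,
                      seed: int | np.random.Generator = 0,
                      rate: float = NOMINAL_RATE_HZ,
                      amp_scale: float = 1.0,
                      freq_scale: float = 1.0) -> pd.DataFrame:
    """Generate one labelled activity segment at the nominal rate.

    Deterministic given the seed; each sinusoid gets a random initial
    phase.  Samples are clipped to stay strictly inside the sensor
    full-scale intervals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    data = {}
    for axis in AXIS_NAMES:
        v = np.full(n, sig.offsets.get(axis, 0.0))
        for freq, amp in sig.components.get(axis, ()):
            phase = rng.uniform(0, 2 * np.pi)
            v = v + amp * amp_scale * np.sin(2 * np.pi * freq * freq_scale * t + phase)
        sigma = sig.noise.get(axis, 0.0)
        if sigma > 0:
            v = v + rng.normal(0.0, sigma, size=n)
        limit = _FULL_SCALE[axis] - _MARGIN[axis]
        data[axis] = np.clip(v, -limit, limit)
    df = pd.DataFrame(data)
    df.insert(0, "t", t)
    df["label"] = sig.label
    return df


def generate_session(script: SessionScript, seed: int = 0,
                     signatures: dict[str, ActivitySignature] | None = None,
                     rate: float = NOMINAL_RATE_HZ
                     ) -> tuple[pd.DataFrame, list[tuple[int, int, str]]]:
    """Generate a full scripted session.

    Returns the concatenated stream (columns t, 9 axes, label) and the
    exact ground-truth intervals as (start_sample, end_sample, label) with
    end exclusive.
    """
    signatures = signatures or default_signatures()
    rng = np.random.default_rng(seed)
    parts: list[pd.DataFrame] = []
    intervals: list[tuple[int, int, str]] = []
    cursor = 0
    for label, spec in script.entries:
        sig = signatures[label]
        if "reps" in spec:
            if sig.rep_duration is None:
                raise ValueError(f"{label} is continuous; give a duration")
            duration = spec["reps"] * sig.rep_duration
        else:
            duration = float(spec["duration"])
        part = generate_activity(sig, duration, rng, rate=rate,
                                 amp_scale=script.amp_jitter,
                                 freq_scale=script.freq_jitter)
        n = len(part)
        intervals.append((cursor, cursor + n, label))
        cursor += n
        parts.append(part)
    stream = pd.concat(parts, ignore_index=True)
    stream["t"] = np.arange(len(stream)) / rate
    return stream, intervals


def default_cohort(n_subjects: int = 10, seed: int = 0, jitter: float = 0.05,
                   protocol: tuple[tuple[str, dict], ...] | None = None,
                   signatures: dict[str, ActivitySignature] | None = None
                   ) -> list[tuple[str, pd.DataFrame, list[tuple[int, int, str]]]]:
    """Generate one scripted session per subject from a master seed.

    Each subject draws an amplitude factor and a frequency factor from
    lognormal-like distributions with spread ``jitter``; jitter 0 makes
    subjects statistically identical.  Returns (subject_id, stream,
    intervals) triples.
    """
    protocol = protocol or default_protocol()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        amp = float(np.exp(rng.normal(0.0, jitter)))
        freq = float(np.exp(rng.normal(0.0, jitter / 2)))
        session_seed = int(rng.integers(0, 2 ** 31 - 1))
        script = SessionScript(entries=protocol, subject=f"s{i}",
                               amp_jitter=amp, freq_jitter=freq)
        stream, intervals = generate_session(script, seed=session_seed,
                                             signatures=signatures)
        cohort.append((script.subject, stream, intervals))
    return cohort


# ---------------------------------------------------------------------------
# Serialization

def save_signatures(signatures: dict[str, ActivitySignature], path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {k: v.to_dict() for k, v in signatures.items()}, indent=2))


def load_signatures(path: str | Path) -> dict[str, ActivitySignature]:
    raw = json.loads(Path(path).read_text())
    return {k: ActivitySignature.from_dict(v) for k, v in raw.items()}


def save_intervals(intervals: Sequence[tuple[int, int, str]], path: str | Path) -> None:
    """Ground truth as TSV: start_sample, end_sample (exclusive), label."""
    with open(path, "w") as fh:
        for start, end, label in intervals:
            fh.write(f"{start}\t{end}\t{label}\n")


def load_intervals(path: str | Path) -> list[tuple[int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        start, end, label = line.split("\t")
        out.append((int(start), int(end), label))
    return out
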