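"""Dual-mode streaming controller with an energy false-detection filter.

Two recognizers are trained on the same wristband stream but never run at
the same time: a daily-activity model on 2 s windows and an exercise model
on 6 s windows.  The daily model carries one extra "switch" class — a
dedicated gesture the wearer performs to start a training session.  While
in exercise mode nothing in the stream can stop the session explicitly;
instead each exercise prediction is checked against the energy recorded
for that exercise during training, a prediction whose window energy
deviates by more than tau dispersions is a false detection, and K
consecutive false detections hand control back to the daily model.

Window buffers are cleared on every mode switch, so the first exercise
prediction arrives one full window (6 s) after the switch gesture; this
avoids classifying windows that straddle two activities.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from wristhar.codec import ImuSample
from wristhar.features import CATALOG, FeatureCatalog, extract_features, window_energy
from wristhar.recognition import TrainedModel, predict
from wristhar.windows import DAILY_CONFIG, EXERCISE_CONFIG, WindowAssembler, WindowConfig

logger = logging.getLogger(__name__)

SWITCH_LABEL = "switch"


class Mode(enum.Enum):
    DAILY = "daily"
    EXERCISE = "exercise"


@dataclass(frozen=True)
class EnergyProfile:
    """Per-exercise mean and dispersion of the window energy feature."""

    mean: dict[str, float]
    std: dict[str, float]

    @classmethod
    def fit(cls, labels, energies) -> "EnergyProfile":
        labels = np.asarray(labels)
        energies = np.asarray(energies, dtype=float)
        mean, std = {}, {}
        for c in np.unique(labels):
            e = energies[labels == c]
            mean[str(c)] = float(e.mean())
            std[str(c)] = float(e.std(ddof=1)) if e.size > 1 else 0.0
        return cls(mean, std)


@dataclass(frozen=True)
class SwitchPolicy:
    """Switch gesture label, energy tolerance tau, revert threshold K."""

    switch_label: str = SWITCH_LABEL
    tau: float = 3.0
    revert_after: int = 3

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.revert_after < 1:
            raise ValueError("revert_after must be >= 1")


def is_false_detection(label: str, window_energy_value: float,
                       profile: EnergyProfile, tau: float) -> bool:
    """True iff the window energy is unrelated to the class's training energy.

    The test is |e - mean_c| > tau * std_c; a class with zero dispersion
    accepts only an exact energy match.
    """
    mean = profile.mean[label]
    std = profile.std[label]
    if std == 0.0:
        return window_energy_value != mean
    return abs(window_energy_value - mean) > tau * std


@dataclass
class RecognitionEvent:
    """One emitted prediction: timestamp, mode, label, votes, energy."""

    t: float
    mode: str
    label: str
    votes: dict[str, float]
    energy: float | None
    accepted: bool

    def to_json(self) -> str:
        return json.dumps({
            "t": self.t, "mode": self.mode, "label": self.label,
            "votes": self.votes, "energy": self.energy,
            "accepted": self.accepted,
        })


class DualModeController:
    """State machine running the two recognizers on one sample stream."""

    def __init__(self, daily_model: TrainedModel, exercise_model: TrainedModel,
                 profile: EnergyProfile, policy: SwitchPolicy = SwitchPolicy(),
                 daily_cfg: WindowConfig = DAILY_CONFIG,
                 exercise_cfg: WindowConfig = EXERCISE_CONFIG,
                 catalog: FeatureCatalog = CATALOG) -> None:
        for name, model in (("daily", daily_model), ("exercise", exercise_model)):
            if not hasattr(model.forest, "estimators_"):
                raise ValueError(f"{name} model is not trained")
        if policy.switch_label not in daily_model.classes:
            raise ValueError(
                f"daily model lacks the switch class {policy.switch_label!r}"
            )
        for model in (daily_model, exercise_model):
            if model.feature_names and tuple(model.feature_names) != catalog.names:
                raise ValueError("models must be trained on the full feature catalog")
        missing = [c for c in exercise_model.classes if c not in profile.mean]
        if missing:
            raise ValueError(f"energy profile missing classes: {missing}")
        self.daily_model = daily_model
        self.exercise_model = exercise_model
        self.profile = profile
        self.policy = policy
        self.catalog = catalog
        self.mode = Mode.DAILY
        self.false_count = 0
        self._daily_buf = WindowAssembler(daily_cfg)
        self._exercise_buf = WindowAssembler(exercise_cfg)

    def _switch_to(self, mode: Mode) -> None:
        logger.info("mode switch %s -> %s", self.mode.value, mode.value)
        self.mode = mode
        self.false_count = 0
        self._daily_buf.reset()
        self._exercise_buf.reset()

    def step(self, sample: ImuSample) -> RecognitionEvent | None:
        """Feed one sample; return an event when a window closes."""
        if self.mode is Mode.DAILY:
            w = self._daily_buf.push(sample)
            self._exercise_buf._last_t = sample.t  # keep gap detector honest
            if w is None:
                return None
            fv = extract_features(w, self.catalog)
            label, votes = predict(self.daily_model, fv)
            event = RecognitionEvent(t=w.t0, mode=Mode.DAILY.value, label=label,
                                     votes=votes, energy=None, accepted=True)
            if label == self.policy.switch_label:
                self._switch_to(Mode.EXERCISE)
            return event

        w = self._exercise_buf.push(sample)
        self._daily_buf._last_t = sample.t
        if w is None:
            return None
        fv = extract_features(w, self.catalog)
        label, votes = predict(self.exercise_model, fv)
        e = window_energy(fv, self.catalog)
        false = is_false_detection(label, e, self.profile, self.policy.tau)
        event = RecognitionEvent(t=w.t0, mode=Mode.EXERCISE.value, label=label,
                                 votes=votes, energy=e, accepted=not false)
        if false:
            self.false_count += 1
            if self.false_count >= self.policy.revert_after:
                self._switch_to(Mode.DAILY)
        else:
            self.false_count = 0
        return event

    def run(self, samples: Iterable[ImuSample]) -> Iterator[RecognitionEvent]:
        for s in samples:
            event = self.step(s)
            if event is not None:
                yield event
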