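"""Random-forest recognition: configuration, metrics and feature reduction.

A random forest is an ensemble of B decision trees; each split considers F
randomly drawn candidate features and the final decision is a majority vote
over the trees.  The classical recommendations for F given m features are

    F = floor(log2 m) + 1        (Breiman's rule)
    F = floor(sqrt(m) / 2)
    F = floor(sqrt(m))

Tree induction is delegated to scikit-learn's ``RandomForestClassifier``
(B, F, the split criterion and the seed are passed through); the majority
vote with its lexicographic tie-break is computed here from the individual
trees' predictions.

Evaluation metrics are accuracy, per-class precision/recall/F, and Cohen's
kappa k = (P_o - P_e) / (1 - P_e) where P_o is the observed agreement and
P_e the agreement expected by chance from the confusion-matrix marginals.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)


class FRule(enum.Enum):
    """Rule mapping feature count m to the per-split candidate count F."""

    LOG2M_PLUS_1 = "log2m+1"
    HALF_SQRT_M = "half_sqrt_m"
    SQRT_M = "sqrt_m"


class SplitCriterion(enum.Enum):
    GINI = "gini"
    INFO_GAIN = "entropy"


def resolve_F(m: int, rule: FRule) -> int:
    """Resolve an F rule to a concrete candidate count in [1, m]."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if rule is FRule.LOG2M_PLUS_1:
        f = math.floor(math.log2(m)) + 1
    elif rule is FRule.SQRT_M:
        f = math.floor(math.sqrt(m))
    elif rule is FRule.HALF_SQRT_M:
        f = math.floor(math.sqrt(m) / 2)
    else:  # pragma: no cover
        raise ValueError(rule)
    return int(min(max(f, 1), m))


@dataclass(frozen=True)
class RFConfig:
    """Forest size B, F rule, split criterion and seed."""

    B: int = 100
    F_rule: FRule = FRule.HALF_SQRT_M
    criterion: SplitCriterion = SplitCriterion.GINI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


def gini(p: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_i^2) of a class distribution."""
    p = np.asarray(p, dtype=float)
    return float(1.0 - np.sum(p ** 2))


def info_entropy(p: Sequence[float]) -> float:
    """Shannon entropy sum(-p_i log2 p_i), with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


@dataclass
class LabeledDataset:
    """Feature matrix, labels and subject identifiers for training."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("inconsistent row counts")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[mask], self.y[mask], self.subjects[mask],
                              self.feature_names)


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to use it."""

    forest: RandomForestClassifier
    classes: tuple[str, ...]
    config: RFConfig
    resolved_F: int
    feature_names: tuple[str, ...] = ()


def train(data: LabeledDataset, cfg: RFConfig = RFConfig()) -> TrainedModel:
    """Fit a B-tree forest with F candidate features per split."""
    classes = np.unique(data.y)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    F = resolve_F(data.m, cfg.F_rule)
    forest = RandomForestClassifier(
        n_estimators=cfg.B,
        max_features=F,
        criterion=cfg.criterion.value,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(data.X, data.y)
    return TrainedModel(forest=forest, classes=tuple(str(c) for c in classes),
                        config=cfg, resolved_F=F,
                        feature_names=data.feature_names)


def _tree_votes(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-class vote counts, shape (n_rows, n_classes), classes sorted."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    counts = np.zeros((X.shape[0], len(model.classes)), dtype=int)
    for est in model.forest.estimators_:
        idx = est.predict(X).astype(int)  # trees predict class indices
        for row, k in enumerate(idx):
            counts[row, k] += 1
    return counts


def predict(model: TrainedModel, fv: np.ndarray) -> tuple[str, dict[str, float]]:
    """Majority vote over the trees for one feature vector.

    Ties break toward the lexicographically first class (classes are kept
    sorted, so the first argmax wins).  Returns the label and the per-class
    vote fractions, which sum to 1.
    """
    counts = _tree_votes(model, fv)[0]
    winner = model.classes[int(np.argmax(counts))]
    fractions = {c: counts[i] / counts.sum() for i, c in enumerate(model.classes)}
    return winner, fractions


def predict_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Majority-vote labels for many rows (lexicographic tie-break)."""
    counts = _tree_votes(model, X)
    return np.array([model.classes[i] for i in counts.argmax(axis=1)])


# ---------------------------------------------------------------------------
# Confusion matrix and metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    """Per-class prediction counts; rows are true labels, columns predicted."""

    labels: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_counts(cls, counts, labels) -> "ConfusionMatrix":
        counts = np.asarray(counts, dtype=int)
        labels = tuple(str(x) for x in labels)
        if counts.shape != (len(labels), len(labels)):
            raise ValueError("counts must be square and match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        return cls(labels, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _i(self, label: str) -> int:
        return self.labels.index(label)

    def tp(self, label: str) -> int:
        i = self._i(label)
        return int(self.counts[i, i])

    def fp(self, label: str) -> int:
        i = self._i(label)
        return int(self.counts[:, i].sum() - self.counts[i, i])

    def fn(self, label: str) -> int:
        i = self._i(label)
        return int(self.counts[i, :].sum() - self.counts[i, i])

    def tn(self, label: str) -> int:
        return self.total - self.tp(label) - self.fp(label) - self.fn(label)

    def support(self, label: str) -> int:
        return int(self.counts[self._i(label), :].sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label sets differ")
        return ConfusionMatrix(self.labels, self.counts + other.counts)


def confusion(labels, predictions, classes: Sequence[str] | None = None) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([labels, predictions]))
    classes = tuple(str(c) for c in classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(labels, predictions):
        counts[index[str(t)], index[str(p)]] += 1
    return ConfusionMatrix(classes, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def precision_recall_f(cm: ConfusionMatrix, label: str) -> tuple[float, float, float]:
    """Per-class precision, recall and F-score.

    An undefined ratio (no predicted or no true instances of the class) is
    reported as 0.
    """
    tp, fp, fn = cm.tp(label), cm.fp(label), cm.fn(label)
    if tp + fp == 0:
        logger.debug("no predictions for class %s; precision set to 0", label)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def f_measure(cm: ConfusionMatrix, average: str = "weighted") -> float:
    """Class-averaged F-score: support-weighted by default, or macro."""
    fs = np.array([precision_recall_f(cm, c)[2] for c in cm.labels])
    if average == "macro":
        return float(fs.mean())
    if average == "weighted":
        w = np.array([cm.support(c) for c in cm.labels], dtype=float)
        if w.sum() == 0:
            raise ValueError("empty confusion matrix")
        return float(np.sum(fs * w) / w.sum())
    raise ValueError(f"unknown average {average!r}")


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (P_o - P_e) / (1 - P_e).

    P_e is the product of row and column marginals summed over classes.  In
    the degenerate case P_e = 1 (a single effective class) kappa is defined
    as 0.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / total
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    pe = float(np.sum(row * col)) / total ** 2
    if pe == 1.0:
        logger.debug("degenerate single-class kappa; returning 0")
        return 0.0
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class MetricsReport:
    """Summary metrics of one evaluation."""

    accuracy: float
    f_weighted: float
    f_macro: float
    kappa: float
    p_observed: float
    p_expected: float
    per_class: dict[str, tuple[float, float, float]]
    n: int
    n_features: int = 0

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, n_features: int = 0) -> "MetricsReport":
        total = cm.total
        po = float(np.trace(cm.counts)) / total
        row = cm.counts.sum(axis=1)
        col = cm.counts.sum(axis=0)
        pe = float(np.sum(row * col)) / total ** 2
        return cls(
            accuracy=accuracy(cm),
            f_weighted=f_measure(cm, "weighted"),
            f_macro=f_measure(cm, "macro"),
            kappa=cohen_kappa(cm),
            p_observed=po,
            p_expected=pe,
            per_class={c: precision_recall_f(cm, c) for c in cm.labels},
            n=total,
            n_features=n_features,
        )

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f_weighted": self.f_weighted,
            "f_macro": self.f_macro,
            "kappa": self.kappa,
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "per_class": {c: list(v) for c, v in self.per_class.items()},
            "n": self.n,
            "n_features": self.n_features,
        }


# ---------------------------------------------------------------------------
# Feature reduction

@dataclass
class PCAReducer:
    """Standardize-then-project transform fitted on training rows only."""

    scaler: StandardScaler
    pca: PCA

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))


def reduce_features_pca(X: np.ndarray, target: int) -> tuple[np.ndarray, PCAReducer]:
    """Fit a ``target``-component PCA on standardized features."""
    X = np.asarray(X, dtype=float)
    if target > X.shape[1]:
        raise ValueError(f"target {target} exceeds feature count {X.shape[1]}")
    scaler = StandardScaler().fit(X)
    pca = PCA(n_components=target, random_state=0).fit(scaler.transform(X))
    reducer = PCAReducer(scaler, pca)
    return reducer.transform(X), reducer


def reduce_features_supervised(X: np.ndarray, y: np.ndarray,
                               max_features: int | None = None) -> list[int]:
    """Correlation-based greedy forward feature selection.

    Selects the subset maximizing the merit

        k * mean|r_cf| / sqrt(k + k(k-1) * mean|r_ff|)

    where r_cf are feature-class correlations and r_ff pairwise correlations
    among selected features.  The class correlation of a feature is the
    largest absolute Pearson correlation with any one-vs-rest class
    indicator, so it does not depend on an arbitrary numeric class
    encoding.  Selection stops when no candidate improves the merit.  This
    is a reconstruction of the classic CFS-style supervised filter; the
    exact algorithm behind the original toolkit default is not published,
    so the subset should be treated as approximate.
    """
    X = np.asarray(X, dtype=float)
    classes, y_num = np.unique(np.asarray(y), return_inverse=True)
    m = X.shape[1]
    if max_features is None:
        max_features = m

    def safe_corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(abs(np.corrcoef(a, b)[0, 1]))

    indicators = [(y_num == k).astype(float) for k in range(len(classes))]
    r_cf = np.array([
        max(safe_corr(X[:, j], ind) for ind in indicators) for j in range(m)
    ])
    selected: list[int] = []
    r_ff_sum = 0.0  # sum of |corr| over selected pairs
    best_merit = 0.0
    while len(selected) < max_features:
        best_j, best_candidate_merit, best_pair_sum = -1, best_merit, 0.0
        for j in range(m):
            if j in selected:
                continue
            k = len(selected) + 1
            pair_sum = r_ff_sum + sum(
                safe_corr(X[:, j], X[:, i]) for i in selected
            )
            mean_cf = (r_cf[selected].sum() + r_cf[j]) / k
            mean_ff = pair_sum / (k * (k - 1) / 2) if k > 1 else 0.0
            merit = k * mean_cf / math.sqrt(k + k * (k - 1) * mean_ff)
            if merit > best_candidate_merit + 1e-12:
                best_j, best_candidate_merit, best_pair_sum = j, merit, pair_sum
        if best_j < 0:
            break
        selected.append(best_j)
        r_ff_sum = best_pair_sum
        best_merit = best_candidate_merit
    return selected


# ---------------------------------------------------------------------------
# Persistence

MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a versioned archive."""
    payload = {
        "version": MODEL_FORMAT_VERSION,
        "config": {
            "B": model.config.B,
            "F_rule": model.config.F_rule.value,
            "criterion": model.config.criterion.value,
            "seed": model.config.seed,
        },
        "classes": list(model.classes),
        "resolved_F": model.resolved_F,
        "feature_names": list(model.feature_names),
        "forest": model.forest,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {payload.get('version')}")
    cfg = RFConfig(
        B=payload["config"]["B"],
        F_rule=FRule(payload["config"]["F_rule"]),
        criterion=SplitCriterion(payload["config"]["criterion"]),
        seed=payload["config"]["seed"],
    )
    return TrainedModel(
        forest=payload["forest"],
        classes=tuple(payload["classes"]),
        config=cfg,
        resolved_F=payload["resolved_F"],
        feature_names=tuple(payload["feature_names"]),
    )
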