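"""Forest configuration, impurity formulas, metrics, feature reduction."""

from types import SimpleNamespace

import numpy as np
import pytest
import sklearn.metrics

from wristhar.recognition import (
    ConfusionMatrix,
    FRule,
    LabeledDataset,
    RFConfig,
    TrainedModel,
    accuracy,
    cohen_kappa,
    confusion,
    f_measure,
    gini,
    info_entropy,
    load_model,
    precision_recall_f,
    predict,
    predict_batch,
    reduce_features_pca,
    reduce_features_supervised,
    resolve_F,
    save_model,
    train,
)


@pytest.mark.parametrize("m, rule, expected", [
    (105, FRule.LOG2M_PLUS_1, 7),
    (105, FRule.SQRT_M, 10),
    (105, FRule.HALF_SQRT_M, 5),
    (1, FRule.LOG2M_PLUS_1, 1),
    (1, FRule.SQRT_M, 1),
    (1, FRule.HALF_SQRT_M, 1),
])
def test_resolve_F(m, rule, expected):
    assert resolve_F(m, rule) == expected


@pytest.mark.parametrize("p, g, e", [
    ([1.0], 0.0, 0.0),
    ([0.5, 0.5], 0.5, 1.0),
    ([0.25] * 4, 0.75, 2.0),
])
def test_impurity_examples(p, g, e):
    assert gini(p) == pytest.approx(g)
    assert info_entropy(p) == pytest.approx(e)


def test_impurity_maximized_at_uniform(rng):
    for k in (2, 3, 5):
        uniform = np.full(k, 1 / k)
        for _ in range(20):
            p = rng.dirichlet(np.ones(k))
            assert gini(p) <= gini(uniform) + 1e-12
            assert info_entropy(p) <= info_entropy(uniform) + 1e-12


# --- training and prediction ------------------------------------------------

def gaussian_dataset(rng, n=200, sep=10.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, 5)),
                   rng.normal(sep, 1, (n // 2, 5))])
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    return LabeledDataset(X, y, np.zeros(n, dtype=int))


def test_train_separates_gaussians(rng):
    ds = gaussian_dataset(rng)
    model = train(ds, RFConfig(B=10, seed=0))
    assert (predict_batch(model, ds.X) == ds.y).all()


def test_train_is_deterministic(rng):
    ds = gaussian_dataset(rng, sep=1.5)
    a = predict_batch(train(ds, RFConfig(B=20, seed=7)), ds.X)
    b = predict_batch(train(ds, RFConfig(B=20, seed=7)), ds.X)
    np.testing.assert_array_equal(a, b)


def test_single_class_rejected(rng):
    X = rng.normal(size=(10, 3))
    with pytest.raises(ValueError, match="2 classes"):
        train(LabeledDataset(X, np.array(["a"] * 10), np.zeros(10)))


def stub_model(tree_outcomes, classes):
    """A forest whose trees return fixed class indices (votes under test)."""
    estimators = [
        SimpleNamespace(predict=lambda X, k=k: np.full(len(X), k, dtype=float))
        for k in tree_outcomes
    ]
    return TrainedModel(
        forest=SimpleNamespace(estimators_=estimators),
        classes=tuple(classes), config=RFConfig(B=len(tree_outcomes)),
        resolved_F=1,
    )


def test_majority_vote_three_trees():
    # trees voting (c1, c2, c1) elect c1 with vote fraction 2/3
    model = stub_model([0, 1, 0], ["c1", "c2"])
    label, votes = predict(model, np.zeros(4))
    assert label == "c1"
    assert votes == {"c1": pytest.approx(2 / 3), "c2": pytest.approx(1 / 3)}
    assert sum(votes.values()) == pytest.approx(1.0)


def test_tie_breaks_lexicographically():
    model = stub_model([0, 1], ["apple", "banana"])
    label, _ = predict(model, np.zeros(4))
    assert label == "apple"
    model = stub_model([1, 0], ["apple", "banana"])
    label, _ = predict(model, np.zeros(4))
    assert label == "apple"


def test_unanimous_vote():
    model = stub_model([1, 1, 1], ["a", "b"])
    label, votes = predict(model, np.zeros(2))
    assert label == "b" and votes["b"] == 1.0


# --- confusion matrix and metrics ------------------------------------------

def test_confusion_basics():
    y = ["a", "b", "a", "c"]
    cm = confusion(y, y)
    assert np.trace(cm.counts) == cm.total == 4
    cm2 = confusion(["a", "a", "b"], ["a", "b", "a"])
    assert cm2.total == 3
    swapped = confusion(["a", "b", "a"], ["a", "a", "b"])
    np.testing.assert_array_equal(cm2.counts, swapped.counts.T)


def test_accuracy_examples():
    cm = ConfusionMatrix.from_counts([[8, 1], [2, 9]], ["neg", "pos"])
    assert accuracy(cm) == pytest.approx(0.85)  # (TP+TN)/(TP+TN+FP+FN)
    perfect = ConfusionMatrix.from_counts([[5, 0], [0, 5]], ["a", "b"])
    assert accuracy(perfect) == 1.0
    with pytest.raises(ValueError):
        accuracy(ConfusionMatrix.from_counts([[0, 0], [0, 0]], ["a", "b"]))


def test_precision_recall_f_hand_example():
    # class a: TP=8, FN=8, FP=2 -> P=0.8, R=0.5, F=8/13
    cm = ConfusionMatrix.from_counts([[8, 8], [2, 10]], ["a", "b"])
    p, r, f = precision_recall_f(cm, "a")
    assert (p, r) == (pytest.approx(0.8), pytest.approx(0.5))
    assert f == pytest.approx(8 / 13)
    perfect = ConfusionMatrix.from_counts([[5, 0], [0, 5]], ["a", "b"])
    assert precision_recall_f(perfect, "a") == (1.0, 1.0, 1.0)
    absent = ConfusionMatrix.from_counts([[5, 0], [0, 0]], ["a", "b"])
    assert precision_recall_f(absent, "b") == (0.0, 0.0, 0.0)


def test_cohen_kappa_examples():
    cm = ConfusionMatrix.from_counts([[45, 5], [15, 35]], ["a", "b"])
    assert cohen_kappa(cm) == pytest.approx(0.6)  # Po=0.8, Pe=0.5
    perfect = ConfusionMatrix.from_counts([[5, 0], [0, 5]], ["a", "b"])
    assert cohen_kappa(perfect) == 1.0
    chance = ConfusionMatrix.from_counts([[25, 25], [25, 25]], ["a", "b"])
    assert cohen_kappa(chance) == 0.0
    degenerate = ConfusionMatrix.from_counts([[7, 0], [0, 0]], ["a", "b"])
    assert cohen_kappa(degenerate) == 0.0


def test_metrics_match_sklearn_oracle(rng):
    """Count-everything cross-check on random label/prediction pairs."""
    classes = np.array(["a", "b", "c", "d"])
    for _ in range(10):
        y = classes[rng.integers(0, 4, 100)]
        p = classes[rng.integers(0, 4, 100)]
        cm = confusion(y, p, classes=classes)
        assert accuracy(cm) == pytest.approx(sklearn.metrics.accuracy_score(y, p))
        assert cohen_kappa(cm) == pytest.approx(
            sklearn.metrics.cohen_kappa_score(y, p))
        assert f_measure(cm, "weighted") == pytest.approx(
            sklearn.metrics.f1_score(y, p, average="weighted", zero_division=0))
        assert f_measure(cm, "macro") == pytest.approx(
            sklearn.metrics.f1_score(y, p, average="macro", zero_division=0))


# --- feature reduction ------------------------------------------------------

def test_pca_reduction(rng):
    X = rng.normal(size=(80, 30))
    Xt, reducer = reduce_features_pca(X, 15)
    assert Xt.shape == (80, 15)
    # train-fitted transform applies unchanged to new rows
    X_new = rng.normal(size=(5, 30))
    np.testing.assert_array_equal(reducer.transform(X_new), reducer.transform(X_new))
    with pytest.raises(ValueError):
        reduce_features_pca(X, 31)


def test_pca_reconstruction_error_non_increasing(rng):
    X = rng.normal(size=(60, 12)) @ rng.normal(size=(12, 12))
    errors = []
    for target in (2, 6, 12):
        Xt, reducer = reduce_features_pca(X, target)
        back = reducer.pca.inverse_transform(Xt)
        errors.append(np.linalg.norm(back - reducer.scaler.transform(X)))
    assert errors[0] >= errors[1] >= errors[2]
    assert errors[2] == pytest.approx(0.0, abs=1e-8)  # identity at target=m


def test_supervised_selection_properties(rng):
    y = rng.integers(0, 3, 120)
    X = rng.normal(size=(120, 8))
    X[:, 4] = y  # a feature equal to the label encoding
    selected = reduce_features_supervised(X, y)
    assert 4 in selected and selected[0] == 4
    assert len(selected) == len(set(selected)) <= 8


# --- persistence ------------------------------------------------------------

def test_model_save_load_roundtrip(tmp_path, rng):
    ds = gaussian_dataset(rng, sep=2.0)
    model = train(ds, RFConfig(B=10, seed=3))
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    assert back.classes == model.classes
    assert back.config == model.config
    np.testing.assert_array_equal(predict_batch(back, ds.X),
                                  predict_batch(model, ds.X))
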