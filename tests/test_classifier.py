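"""Sigmoid-neuron training, prediction and cross-validation."""

import math

import numpy as np
import pytest

from shgquant.classifier import (ConfusionMatrix, bce_loss, confusion_counts,
                                 confusion_metrics, kfold_cv, predict,
                                 train_neuron)


def test_bce_known_values():
    assert bce_loss(np.array([1.0]), np.array([0.5])) == \
        pytest.approx(math.log(2.0), abs=1e-15)
    assert bce_loss(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == \
        pytest.approx(0.0, abs=1e-10)  # clipped, not infinite
    assert np.isfinite(bce_loss(np.array([1.0]), np.array([0.0])))


def test_bce_validation():
    with pytest.raises(ValueError, match="binary"):
        bce_loss(np.array([0.5]), np.array([0.5]))
    with pytest.raises(ValueError, match="equal length"):
        bce_loss(np.array([1.0]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="empty"):
        bce_loss(np.array([]), np.array([]))


def separable_data(rng, n=60):
    y = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
    x = np.where(y == 1, rng.normal(0.35, 0.02, n), rng.normal(0.15, 0.02, n))
    return x, y


def test_train_separable_perfect(rng):
    x, y = separable_data(rng)
    model = train_neuron(x, y)
    p, hard = predict(model, x)
    assert (hard == y).all()
    assert model.loss_history[-1] < model.loss_history[0]


def test_training_deterministic(rng):
    x, y = separable_data(rng)
    m1 = train_neuron(x, y)
    m2 = train_neuron(x, y)
    np.testing.assert_array_equal(m1.w, m2.w)
    assert m1.b == m2.b


def test_single_class_rejected(rng):
    x = rng.normal(size=20)
    with pytest.raises(ValueError, match="both classes"):
        train_neuron(x, np.zeros(20, dtype=int))


def test_constant_feature_gives_chance(rng):
    x = np.full(20, 0.3)
    y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
    model = train_neuron(x, y)
    p, hard = predict(model, x)
    # zero-gradient symmetry: probability stays at 0.5, strict rule says 0
    assert np.allclose(p, 0.5)
    assert (hard == 0).all()


def test_predict_dimension_check(rng):
    x, y = separable_data(rng)
    model = train_neuron(x, y)
    with pytest.raises(ValueError, match="dimensionality"):
        predict(model, rng.normal(size=(4, 2)))


def test_confusion_counts():
    cm = confusion_counts(np.array([1, 1, 0, 0, 1]), np.array([1, 0, 0, 1, 1]))
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 1, 1)
    assert cm.total == 5
    both = cm + cm
    assert both.tp == 4 and both.total == 10


def test_confusion_metrics_values():
    m = confusion_metrics(ConfusionMatrix(tp=8, fp=2, tn=6, fn=4))
    assert m["f1"] == pytest.approx(16 / 22)
    assert m["sensitivity"] == pytest.approx(8 / 12)
    assert m["specificity"] == pytest.approx(6 / 8)
    assert m["accuracy"] == pytest.approx(14 / 20)


def test_confusion_metrics_undefined():
    with pytest.raises(ValueError, match="sensitivity undefined"):
        confusion_metrics(ConfusionMatrix(tp=0, fp=1, tn=2, fn=0))
    with pytest.raises(ValueError, match="specificity undefined"):
        confusion_metrics(ConfusionMatrix(tp=3, fp=0, tn=0, fn=1))
    with pytest.raises(ValueError, match="empty"):
        confusion_metrics(ConfusionMatrix())


def test_kfold_partitions_everything(rng):
    x, y = separable_data(rng, n=80)
    report = kfold_cv(x, y, k=10, seed=0)
    assert report.aggregate.total == 80
    assert sum(m.total for m in report.fold_matrices) == 80
    assert len(report.fold_matrices) == 10


def test_kfold_stratified_balance(rng):
    x, y = separable_data(rng, n=80)
    report = kfold_cv(x, y, k=10, seed=0)
    for m in report.fold_matrices:
        assert m.tp + m.fn == 4  # 40 positives over 10 folds
        assert m.tn + m.fp == 4


def test_kfold_perfect_on_separable(rng):
    x, y = separable_data(rng, n=80)
    report = kfold_cv(x, y, k=10, seed=0)
    assert report.f1 == 1.0
    assert report.sensitivity == 1.0
    assert report.specificity == 1.0


def test_kfold_class_too_small_rejected(rng):
    x = rng.normal(size=30)
    y = np.r_[np.ones(5, dtype=int), np.zeros(25, dtype=int)]
    with pytest.raises(ValueError, match=">= k"):
        kfold_cv(x, y, k=10)
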