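"""Loss, training schedule, evaluation metrics and distance matrices."""

import numpy as np
import pytest

from specphenonet.models import Model1DSpec, build_1d_model
from specphenonet.training_eval import (LABEL_ORDER, TrainConfig,
                                        class_distance_matrix, cross_entropy,
                                        evaluate, report_from_predictions,
                                        train)

TINY = Model1DSpec(channel_length=96, stem_filters=4,
                   stage_blocks=(1, 1, 1, 1), stage_filters=(4, 4, 8, 8))


# ---------------------------------------------------------------------------
# cross-entropy

def test_cross_entropy_closed_forms():
    assert cross_entropy(np.array([1.0, 0.0, 0.0, 0.0]), 0) == 0.0
    assert cross_entropy(np.full(4, 0.25), 2) == pytest.approx(np.log(4.0))
    assert cross_entropy(np.array([0.5, 0.2, 0.2, 0.1]), 0) == pytest.approx(
        np.log(2.0))


def test_cross_entropy_batch_mean():
    p = np.array([[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25]])
    assert cross_entropy(p, [0, 1]) == pytest.approx(np.log(4.0) / 2)


def test_cross_entropy_clamps_zero_probability():
    with pytest.warns(UserWarning):
        loss = cross_entropy(np.array([0.0, 1.0, 0.0, 0.0]), 0)
    assert loss == pytest.approx(-np.log(1e-12))


def test_untrained_model_loss_near_ln4():
    model = build_1d_model(TINY, seed=0)
    x = np.random.default_rng(0).normal(size=(32, 4, 96))
    y = np.random.default_rng(1).integers(0, 4, 32)
    loss = cross_entropy(model.forward(x), y)
    assert abs(loss - np.log(4.0)) < 0.3


# ---------------------------------------------------------------------------
# training loop and schedule

def _toy_data(n=32, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4, 96)) * 0.1
    y = np.repeat(np.arange(4), n // 4)
    for c in range(4):
        X[y == c, c, :] += 1.0
    return X, y


def test_history_has_one_record_per_epoch_and_split():
    X, y = _toy_data()
    model = build_1d_model(TINY, seed=1)
    _, history = train(model, X, y, X, y,
                       TrainConfig(epochs=25, batch_size=8, seed=0))
    assert len(history) == 50
    assert {h.split for h in history} == {"train", "test"}
    assert [h.epoch for h in history if h.split == "train"] == list(range(25))


def test_lr_sequence_halves_on_plateau():
    X, y = _toy_data()
    model = build_1d_model(TINY, seed=2)
    _, history = train(model, X, y, X, y,
                       TrainConfig(epochs=12, batch_size=8, seed=0))
    lrs = [h.lr for h in history if h.split == "train"]
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))
    for lr in lrs:
        k = np.log(1e-3 / lr) / np.log(2.0)
        assert k == pytest.approx(round(k), abs=1e-9)
    # accuracy saturates at 1 on this toy set, so a reduction must occur
    assert lrs[-1] <= 5e-4


def test_training_improves_separable_accuracy():
    X, y = _toy_data(seed=3)
    model = build_1d_model(TINY, seed=3)
    _, history = train(model, X, y, X, y,
                       TrainConfig(epochs=25, batch_size=8, seed=1))
    accs = [h.accuracy for h in history if h.split == "train"]
    assert accs[-1] > accs[0]
    assert max(accs) >= 0.75


def test_empty_training_split_errors():
    model = build_1d_model(TINY, seed=0)
    with pytest.raises(ValueError):
        train(model, np.zeros((0, 4, 96)), np.zeros(0, int),
              np.zeros((1, 4, 96)), np.zeros(1, int), TrainConfig(epochs=1))


# ---------------------------------------------------------------------------
# evaluation metrics

class _FixedModel:
    """Stub classifier emitting preset probabilities / embeddings."""

    def __init__(self, probs=None, embeddings=None):
        self._probs = probs
        self._emb = embeddings
        self._i = 0

    def forward(self, x, training=False):
        out = self._probs[self._i:self._i + len(x)]
        self._i += len(x)
        return out

    def embed(self, x):
        out = self._emb[self._i:self._i + len(x)]
        self._i += len(x)
        return out


def _onehot(y):
    p = np.full((len(y), 4), 1e-4)
    p[np.arange(len(y)), y] = 1 - 3e-4
    return p


def test_perfect_predictions_diagonal_confusion():
    y = np.repeat(np.arange(4), 3)
    report = evaluate(_FixedModel(probs=_onehot(y)), np.zeros((12, 1)), y)
    assert report.accuracy == 1.0
    np.testing.assert_array_equal(report.confusion, np.diag([3, 3, 3, 3]))
    assert report.recall == 1.0 and report.f1 == 1.0


def test_single_class_predictions_on_balanced_set():
    y = np.repeat(np.arange(4), 5)
    pred = np.zeros(20, int)
    report = report_from_predictions(y, pred)
    assert report.accuracy == pytest.approx(0.25)
    assert report.confusion[:, 0].sum() == 20


def test_metrics_recomputed_from_confusion_matrix():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 4, 200)
    pred = np.where(rng.random(200) < 0.7, y, rng.integers(0, 4, 200))
    report = report_from_predictions(y, pred)
    C = report.confusion
    assert C.sum() == 200
    assert report.accuracy == pytest.approx(np.trace(C) / C.sum())
    # independent per-class formulas from the raw counts
    for i, label in enumerate(LABEL_ORDER):
        tp = C[i, i]
        fn = C[i].sum() - tp
        fp = C[:, i].sum() - tp
        rec = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert report.per_class.loc[label, "recall"] == pytest.approx(rec)
        assert report.per_class.loc[label, "precision"] == pytest.approx(prec)
        assert report.per_class.loc[label, "f1"] == pytest.approx(f1)
    assert report.recall == pytest.approx(report.per_class.recall.mean())


def test_evaluate_empty_dataset_errors():
    with pytest.raises(ValueError):
        evaluate(_FixedModel(probs=np.zeros((0, 4))), np.zeros((0, 1)),
                 np.zeros(0, int))


# ---------------------------------------------------------------------------
# distance matrix

def test_identical_embeddings_zero_matrix():
    y = np.repeat(np.arange(4), 2)
    emb = np.ones((8, 16))
    dm = class_distance_matrix(_FixedModel(embeddings=emb), np.zeros((8, 1)), y)
    np.testing.assert_allclose(dm.d, 0.0, atol=1e-12)


def test_planted_centroid_offset_recovered():
    y = np.repeat(np.arange(4), 4)
    emb = np.zeros((16, 8))
    v = np.zeros(8)
    v[0], v[3] = 3.0, 4.0                      # |v| = 5
    emb[y == 1] += v
    dm = class_distance_matrix(_FixedModel(embeddings=emb), np.zeros((16, 1)), y)
    assert dm[("CNT", "OVC")] == pytest.approx(5.0)
    assert dm[("CNT", "RNC")] == pytest.approx(0.0)


def test_distance_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(0)
    y = np.repeat(np.arange(4), 5)
    dm = class_distance_matrix(_FixedModel(embeddings=rng.normal(size=(20, 6))),
                               np.zeros((20, 1)), y)
    np.testing.assert_allclose(dm.d, dm.d.T)
    np.testing.assert_allclose(np.diag(dm.d), 0.0)
    assert np.all(dm.d >= 0)


def test_distance_matrix_missing_class_errors():
    y = np.repeat(np.arange(3), 4)             # PRC absent
    with pytest.raises(ValueError, match="PRC"):
        class_distance_matrix(_FixedModel(embeddings=np.zeros((12, 4))),
                              np.zeros((12, 1)), y)
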