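"""Training loop, evaluation metrics and the inter-phenotype distance matrix.

Training uses multiclass cross-entropy (natural log) with the Adam optimizer
and a reduce-on-plateau schedule: when test accuracy stops improving for
``plateau_patience`` epochs the learning rate is halved.  Evaluation reports
accuracy, macro recall and macro F1, per-class metrics and the 4 x 4
confusion matrix in the fixed label order (CNT, OVC, RNC, PRC).  Phenotype
distances are Euclidean (or cosine) distances between per-class centroids of
the model's penultimate embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from . import nn
from .models import SpectrumClassifier

#: fixed label order for confusion and distance matrices
LABEL_ORDER = ("CNT", "OVC", "RNC", "PRC")

_P_FLOOR = 1e-12


@dataclass
class TrainConfig:
    epochs: int = 25
    initial_lr: float = 1e-3
    lr_reduce_factor: float = 0.5
    plateau_patience: int = 2
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lr_reduce_factor < 1):
            raise ValueError("lr_reduce_factor must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class LossRecord(NamedTuple):
    epoch: int
    split: str
    loss: float
    accuracy: float
    lr: float


@dataclass
class EvalReport:
    accuracy: float
    recall: float                       # macro
    f1: float                           # macro
    per_class: pd.DataFrame             # precision/recall/f1/support per label
    confusion: np.ndarray               # rows true, cols predicted, LABEL_ORDER

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.tolist(),
            "labels": list(LABEL_ORDER),
        }


@dataclass
class DistanceMatrix:
    labels: tuple = LABEL_ORDER
    d: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def cross_entropy(probabilities: np.ndarray, true_class) -> float:
    """Multiclass cross-entropy, natural logarithm.

    For one sample this is ``-log(p_true)``; for a batch, the mean over
    samples.  Zero (or tiny) true-class probabilities are clamped at 1e-12.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y = np.atleast_1d(np.asarray(true_class, dtype=int))
    p_true = p[np.arange(len(y)), y]
    if np.any(p_true < _P_FLOOR):
        warnings.warn("true-class probability below 1e-12 clamped in cross-entropy")
        p_true = np.maximum(p_true, _P_FLOOR)
    return float(-np.mean(np.log(p_true)))


def _loss_grad(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean CE)/d(probabilities) for the softmax output."""
    g = np.zeros_like(probs)
    rows = np.arange(len(y))
    g[rows, y] = -1.0 / (np.maximum(probs[rows, y], _P_FLOOR) * len(y))
    return g


def _batch_eval(model, X, y, batch_size, input_adapter=None):
    losses, preds = [], []
    for i in range(0, len(y), batch_size):
        xb = X[i:i + batch_size]
        if input_adapter is not None:
            xb = input_adapter(xb)
        probs = model.forward(xb, training=False)
        losses.append(cross_entropy(probs, y[i:i + batch_size]) * len(probs))
        preds.append(probs.argmax(axis=1))
    return float(np.sum(losses) / len(y)), np.concatenate(preds)


def train(
    model: SpectrumClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cfg: TrainConfig | None = None,
    input_adapter=None,
) -> tuple[SpectrumClassifier, list[LossRecord]]:
    """Fit with Adam + reduce-on-plateau; returns the model and its history.

    ``y`` arrays hold integer class indices in :data:`LABEL_ORDER`.  The
    learning-rate sequence is non-increasing and of the form
    ``initial_lr * lr_reduce_factor**k``.
    """
    cfg = cfg or TrainConfig()
    if len(y_train) == 0:
        raise ValueError("training split is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.initial_lr)
    history: list[LossRecord] = []
    best_acc = -np.inf
    stall = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(y_train))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = X_train[idx]
            if input_adapter is not None:
                xb = input_adapter(xb)
            yb = y_train[idx]
            probs = model.forward(xb, training=True)
            loss = cross_entropy(probs, yb)
            opt.zero_grad()
            model.backward(_loss_grad(probs, yb))
            opt.step()
            ep_loss += loss * len(yb)
            ep_correct += int((probs.argmax(axis=1) == yb).sum())
        train_loss = ep_loss / len(y_train)
        train_acc = ep_correct / len(y_train)
        test_loss, test_pred = _batch_eval(model, X_test, y_test,
                                           cfg.batch_size, input_adapter)
        test_acc = float(np.mean(test_pred == y_test))
        history.append(LossRecord(epoch, "train", train_loss, train_acc, opt.lr))
        history.append(LossRecord(epoch, "test", test_loss, test_acc, opt.lr))
        # reduce-on-plateau on the test accuracy
        if test_acc > best_acc + 1e-12:
            best_acc = test_acc
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                opt.lr *= cfg.lr_reduce_factor
                stall = 0
    return model, history


def history_frame(history: list[LossRecord]) -> pd.DataFrame:
    return pd.DataFrame(history)


def evaluate(
    model: SpectrumClassifier,
    X: np.ndarray,
    y: np.ndarray,
    batch_size: int = 8,
    input_adapter=None,
) -> EvalReport:
    """Accuracy, macro recall/F1, per-class metrics and the confusion matrix."""
    if len(y) == 0:
        raise ValueError("evaluation dataset is empty")
    _, preds = _batch_eval(model, X, y, batch_size, input_adapter)
    return report_from_predictions(np.asarray(y), preds)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    idx = np.arange(len(LABEL_ORDER))
    conf = _sk_confusion(y_true, y_pred, labels=idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=idx, zero_division=0
        )
        _, macro_rec, macro_f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=idx, average="macro", zero_division=0
        )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=list(LABEL_ORDER),
    )
    accuracy = float(np.trace(conf) / conf.sum())
    return EvalReport(accuracy=accuracy, recall=float(macro_rec),
                      f1=float(macro_f1), per_class=per_class, confusion=conf)


def class_distance_matrix(
    model: SpectrumClassifier,
    X: np.ndarray,
    y: np.ndarray,
    metric: str = "euclidean",
    batch_size: int = 8,
    input_adapter=None,
) -> DistanceMatrix:
    """Pairwise distances between per-class centroids of embeddings.

    The feature space is the model's penultimate layer; the metric defaults
    to Euclidean (``"cosine"`` is the alternative).  Every class must be
    represented in ``(X, y)``.
    """
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unsupported metric {metric!r}")
    y = np.asarray(y)
    embeddings = []
    for i in range(0, len(y), batch_size):
        xb = X[i:i + batch_size]
        if input_adapter is not None:
            xb = input_adapter(xb)
        embeddings.append(model.embed(xb))
    E = np.concatenate(embeddings)
    centroids = []
    for ci, label in enumerate(LABEL_ORDER):
        mask = y == ci
        if not mask.any():
            raise ValueError(f"class {label} has no samples in the dataset")
        centroids.append(E[mask].mean(axis=0))
    d = cdist(np.stack(centroids), np.stack(centroids), metric=metric)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels=LABEL_ORDER, d=d)
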