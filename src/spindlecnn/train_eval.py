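"""Training with the stepped AdamW schedule, subject-grouped five-fold
cross-validation, and the five-metric evaluation suite.

The optimizer schedule is ``lr(e) = lr0 × 0.75^floor(e/3)`` — the learning
rate is multiplied by 0.75 every three epochs — with AdamW (decoupled weight
decay) and two-class cross-entropy on the softmax outputs. The default
``lr0=0.1`` is aggressive for AdamW; the trainer aborts with a diagnostic on
a non-finite loss, and 0.001 is a robust alternative if a run diverges on
harder data.

Metrics are the standard confusion-matrix quartet plus AUC::

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 · precision · recall / (precision + recall)

computed for the spindle class at the argmax (0.5) threshold, and AUC is the
Mann–Whitney rank statistic on the spindle-class probability: the fraction
of (positive, negative) pairs ranked correctly, ties counted one half.

"Cross-subject" evaluation means folds partition *subjects*: no subject
contributes windows to both the train and test side of a fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import model as model_mod
from .model import CNNSpec, TrainedModel, build_model
from .nn import AdamW, softmax, softmax_cross_entropy
from .windowing import WindowSet

__all__ = [
    "TrainConfig", "EvalReport", "learning_rate_at", "make_folds",
    "train", "predict", "compute_metrics", "evaluate_model", "cross_validate",
]

METRIC_NAMES = ["accuracy", "recall", "f1", "precision", "auc"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 128
    lr0: float = 0.1
    lr_decay_factor: float = 0.75
    lr_decay_every_epochs: int = 3
    weight_decay: float = 0.01
    seed: int = 0
    fold_grouping: str = "by_subject"  # or "by_window"

    def __post_init__(self) -> None:
        if self.fold_grouping not in ("by_subject", "by_window"):
            raise ValueError(f"unknown fold_grouping {self.fold_grouping!r}")


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Closed form of the stepped schedule: lr0 × factor^floor(e/every)."""
    return config.lr0 * config.lr_decay_factor ** (
        epoch // config.lr_decay_every_epochs
    )


def make_folds(
    window_set: WindowSet, k: int = 5, grouping: str = "by_subject", seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition windows into k folds; returns (train_idx, test_idx) pairs.

    ``by_subject`` partitions the subjects (no subject spans train and test
    of the same fold); ``by_window`` partitions windows directly.
    """
    rng = np.random.default_rng(seed)
    n = len(window_set)
    if grouping == "by_subject":
        subjects = np.array(sorted(set(window_set.subject_id)))
        if len(subjects) < k:
            raise ValueError(
                f"{len(subjects)} subject(s) cannot form {k} subject-grouped folds"
            )
        rng.shuffle(subjects)
        folds = []
        for chunk in np.array_split(subjects, k):
            test_mask = np.isin(window_set.subject_id, chunk)
            folds.append((np.flatnonzero(~test_mask), np.flatnonzero(test_mask)))
        return folds
    perm = rng.permutation(n)
    return [
        (np.setdiff1d(perm, chunk, assume_unique=True), np.sort(chunk))
        for chunk in np.array_split(perm, k)
    ]


def train(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig,
    log: list | None = None,
) -> TrainedModel:
    """Train in place; appends per-epoch (epoch, lr, loss, accuracy) to
    ``log``. Aborts on a non-finite loss (divergence)."""
    rng = np.random.default_rng(config.seed)
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[:, None, :]
    y = np.asarray(y, dtype=np.int64)
    n = len(y)
    opt = AdamW(model.net, lr=config.lr0, weight_decay=config.weight_decay)
    for epoch in range(config.epochs):
        opt.lr = learning_rate_at(config, epoch)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.net.forward(X[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: training diverged "
                    f"(lr0={config.lr0}; consider 0.001)"
                )
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        if log is not None:
            log.append(
                {
                    "epoch": epoch,
                    "lr": opt.lr,
                    "loss": float(np.sum(losses) / n),
                    "train_accuracy": correct / n,
                }
            )
    model.provenance.setdefault("training", []).append(
        {"epochs": config.epochs, "batch_size": config.batch_size,
         "lr0": config.lr0, "seed": config.seed, "n_windows": int(n)}
    )
    return model


def predict(model: TrainedModel, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Spindle-class probabilities, computed in evaluation mode."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[:, None, :]
    out = np.empty(len(X))
    for i in range(0, len(X), batch_size):
        out[i : i + batch_size] = model_mod.forward(model, X[i : i + batch_size])[:, 1]
    return out


def compute_metrics(
    labels: np.ndarray, predicted_labels: np.ndarray, scores: np.ndarray
) -> dict[str, float]:
    """Accuracy, recall, F1, precision (spindle class) and rank-based AUC.

    Raises when recall or AUC is undefined (no positives / only one class);
    F1 is 0 when precision + recall is 0.
    """
    labels = np.asarray(labels).astype(int)
    predicted_labels = np.asarray(predicted_labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    tp = int(np.sum((labels == 1) & (predicted_labels == 1)))
    tn = int(np.sum((labels == 0) & (predicted_labels == 0)))
    fp = int(np.sum((labels == 0) & (predicted_labels == 1)))
    fn = int(np.sum((labels == 1) & (predicted_labels == 0)))
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0:
        raise ValueError("recall undefined: no positive samples in labels")
    if n_neg == 0:
        raise ValueError("AUC undefined: no negative samples in labels")
    accuracy = (tp + tn) / (tp + fp + tn + fn)
    recall = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    # Mann–Whitney rank AUC: P(score_pos > score_neg) + ½ P(tie)
    ranks = rankdata(scores)  # average ranks handle ties as ½ automatically
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {
        "accuracy": accuracy, "recall": recall, "f1": f1,
        "precision": precision, "auc": float(auc),
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
    }


def evaluate_model(model: TrainedModel, X: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Predict with the 0.5/argmax threshold and score all five metrics."""
    scores = predict(model, X)
    return compute_metrics(y, (scores >= 0.5).astype(int), scores)


@dataclass
class EvalReport:
    """Per-fold metrics with mean and standard deviation.

    ``per_fold`` rows carry the five metrics (and confusion counts);
    ``to_dataframe`` mirrors the usual five-rows-plus-aggregate table with a
    final "mean (sd)" row.
    """

    per_fold: list[dict] = field(default_factory=list)
    predictions: list[dict] = field(default_factory=list)  # per-fold y/scores

    def mean(self) -> dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.per_fold])) for m in METRIC_NAMES}

    def std(self) -> dict[str, float]:
        return {m: float(np.std([f[m] for f in self.per_fold])) for m in METRIC_NAMES}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"fold": i + 1, **{m: f[m] for m in METRIC_NAMES}}
            for i, f in enumerate(self.per_fold)
        ]
        mean, std = self.mean(), self.std()
        rows.append(
            {"fold": "mean (sd)", **{
                m: f"{mean[m]:.4f} ({std[m]:.4f})" for m in METRIC_NAMES
            }}
        )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cross_validate(
    window_set: WindowSet,
    cnn_spec: CNNSpec = CNNSpec(),
    train_config: TrainConfig = TrainConfig(),
    k: int = 5,
) -> EvalReport:
    """k-fold cross-validation of the CNN on a window set.

    Folds follow ``train_config.fold_grouping``; each fold trains a fresh
    model (fold-specific seed derived from the config seed) and is scored on
    its held-out windows. Per-fold predictions are retained so every metric
    can be recomputed from them.
    """
    folds = make_folds(
        window_set, k=k, grouping=train_config.fold_grouping,
        seed=train_config.seed,
    )
    report = EvalReport()
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        fold_cfg = replace(train_config, seed=train_config.seed + 1000 * (fold_i + 1))
        mdl = build_model(cnn_spec, seed=fold_cfg.seed)
        train(mdl, window_set.X[train_idx], window_set.y[train_idx], fold_cfg)
        scores = predict(mdl, window_set.X[test_idx])
        y_test = window_set.y[test_idx]
        metrics = compute_metrics(y_test, (scores >= 0.5).astype(int), scores)
        report.per_fold.append(metrics)
        report.predictions.append(
            {"fold": fold_i, "test_idx": test_idx, "y": y_test, "scores": scores}
        )
    return report
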