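"""Per-frame summed cross-entropy objective and reproducible training.

The objective is the cross-entropy summed over every frame of a sample,
L = -sum_{j=1..T} sum_{i=1..C} y_ji log z_ji, and sample losses are summed (not
averaged) across a batch, keeping the per-frame weighting of the objective
uniform regardless of batch size.  Histories record the epoch mean of the
per-sample loss.  There is no validation split or early stopping: the epoch
budget is fixed by the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .dataset import Dataset, loso_splits
from .evaluation import MetricsReport, evaluate
from .model import CEFNet, ModelConfig

__all__ = [
    "TrainConfig",
    "desk_preset",
    "full_preset",
    "frame_cross_entropy",
    "train",
    "predict_dataset",
    "run_loso",
]

LOG_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults are the desk-scale preset."""

    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 16
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def desk_preset(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed)


def full_preset(seed: int = 0) -> TrainConfig:
    """The full-scale protocol: 200 epochs, batch 100, lr 1e-3, Adam."""
    return TrainConfig(epochs=200, batch_size=100, seed=seed)


def frame_cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Summed per-frame cross-entropy of a ``(T, C)`` probability matrix.

    Probabilities on the labelled classes are clamped at 1e-12 before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.ndim != 2 or labels.ndim != 1 or len(probs) != len(labels):
        raise ValueError(
            f"probs (T, C) and labels (T,) lengths must match; got "
            f"{probs.shape} and {labels.shape}"
        )
    if (labels < 0).any() or (labels >= probs.shape[1]).any():
        raise ValueError("labels outside [0, C)")
    p = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(p, LOG_EPS, None)).sum())


def recalibrate_batchnorms(model, x: np.ndarray, batch_size: int) -> None:
    """Re-estimate batch-norm running statistics at the final weights.

    After a short training run the exponential running averages lag the
    weights they normalize for; one deterministic pass over the training set,
    accumulating the cumulative mean of batch statistics, removes that lag.
    Applied identically to the per-frame model and the window classifiers.
    """
    bns = model.batchnorms()
    if not bns:
        return
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    k = 0
    for start in range(0, len(x), batch_size):
        k += 1
        for bn in bns:
            bn.momentum = 1.0 / k
        model.forward(x[start : start + batch_size], training=True)
    for bn in bns:
        bn.momentum = 0.1


def _stack(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    lengths = {s.n_frames for s in dataset}
    if len(lengths) != 1:
        raise ValueError(
            f"batched training requires equal-length samples; got lengths {sorted(lengths)}"
        )
    x = np.stack([s.frames.T for s in dataset])  # (N, 3, T)
    y = np.stack([s.labels for s in dataset])  # (N, T)
    return x, y


def train(
    model: CEFNet, train_data: Dataset, config: TrainConfig
) -> tuple[CEFNet, list[float]]:
    """Minimize the batch-summed per-frame loss; returns (model, history).

    Fully reproducible under ``config.seed`` (shuffling order); weight
    initialization is owned by the model's own seed.
    """
    x, y = _stack(train_data)
    n = len(x)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: list[float] = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, dlogits, _ = nn.cross_entropy_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at epoch {len(history) + 1}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            total += loss
        history.append(total / n)
    recalibrate_batchnorms(model, x, config.batch_size)
    return model, history


def predict_dataset(
    model: CEFNet, dataset: Dataset, chunk: int = 32
) -> list[np.ndarray]:
    """Per-frame argmax predictions for every sample (inference mode)."""
    preds: list[np.ndarray] = []
    samples = dataset.samples
    for start in range(0, len(samples), chunk):
        batch = samples[start : start + chunk]
        x = np.stack([s.frames.T for s in batch])
        logits = model.forward(x, training=False)
        preds.extend(np.argmax(logits, axis=1))
    return preds


def run_loso(
    dataset: Dataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[list[MetricsReport], dict]:
    """Leave-one-subject-out protocol: fresh model per fold, frame-level reports.

    Returns the per-fold reports (ordered by held-out subject) and a cross-fold
    summary whose macro-F1 is the unweighted mean of fold macro-F1 values.
    """
    folds = loso_splits(dataset)
    reports: list[MetricsReport] = []
    for k, (tr, te) in enumerate(folds):
        fold_seed = int(
            np.random.SeedSequence((train_config.seed, k)).generate_state(1)[0]
            % (2**31)
        )
        model = CEFNet(model_config, seed=fold_seed)
        model, _ = train(model, tr, replace(train_config, seed=fold_seed))
        preds = predict_dataset(model, te)
        truths = [s.labels for s in te]
        reports.append(evaluate(preds, truths, dataset.catalog))
    summary = {
        "subjects": dataset.subject_ids,
        "fold_macro_f1": [r.macro_f1 for r in reports],
        "macro_f1_mean": float(np.mean([r.macro_f1 for r in reports])),
        "macro_precision_mean": float(
            np.mean([r.macro_precision for r in reports])
        ),
        "macro_recall_mean": float(np.mean([r.macro_recall for r in reports])),
    }
    return reports, summary
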