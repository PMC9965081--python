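"""The sliding-window (SW) baseline: fixed windows, majority labels, confidence
resolution, frame expansion.

Recordings are cut into fixed-size windows advanced by ``size - overlap``
frames; a window classifier (the same backbone as the per-frame model,
truncated to a single-label head via global average pooling over the window)
is trained on (window, majority-label) pairs.  At prediction time every frame
covered by more than one window takes the class of the covering window with the
highest confidence (its maximum softmax probability; ties go to the earlier
window), and the class is expanded over the window's frames.  Trailing frames
not coverable by a full window inherit the nearest covered frame's assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .dataset import AccelSample, Dataset
from .model import CEFBlock, ModelConfig

__all__ = [
    "WindowSpec",
    "CANONICAL_WINDOW_SPECS",
    "WindowPrediction",
    "segment",
    "window_label",
    "WindowClassifier",
    "train_window_classifier",
    "predict_sw",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window length and overlap in frames; stride = size - overlap."""

    size: int
    overlap: int

    def __post_init__(self) -> None:
        # overlap 0 (stride = size) is admitted for the tiling/reconstruction
        # special case; the canonical baseline variants all overlap by size/2.
        if not 0 <= self.overlap < self.size:
            raise ValueError(
                f"need 0 <= overlap < size, got overlap={self.overlap}, "
                f"size={self.size}"
            )

    @property
    def stride(self) -> int:
        return self.size - self.overlap


#: The three window/overlap pairs of the baseline comparison.
CANONICAL_WINDOW_SPECS: tuple[WindowSpec, ...] = (
    WindowSpec(10, 5),
    WindowSpec(20, 10),
    WindowSpec(40, 20),
)


@dataclass(frozen=True)
class WindowPrediction:
    start: int
    size: int
    class_index: int
    confidence: float


def segment(
    sample: AccelSample, spec: WindowSpec
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Full windows at starts 0, stride, 2*stride, ... while start+size <= T.

    Trailing frames not coverable by a full window are excluded.  Returns
    (start, frames-slice, labels-slice) triples with half-open extents.
    """
    T = sample.n_frames
    if T < spec.size:
        raise ValueError(
            f"sample has {T} frames, shorter than window size {spec.size}"
        )
    out = []
    for start in range(0, T - spec.size + 1, spec.stride):
        out.append(
            (
                start,
                sample.frames[start : start + spec.size],
                sample.labels[start : start + spec.size],
            )
        )
    return out


def window_label(labels_slice: np.ndarray) -> int:
    """Majority (plurality) class of a window; ties -> lowest class index."""
    labels_slice = np.asarray(labels_slice, dtype=np.int64)
    if labels_slice.size == 0:
        raise ValueError("empty label slice")
    return int(np.bincount(labels_slice).argmax())


class WindowClassifier:
    """The per-frame backbone truncated to one label per window.

    Stacked blocks as in the per-frame model, then global average pooling over
    the window's time axis and an affine map to the class scores."""

    def __init__(self, config: ModelConfig, window_size: int, seed: int = 0):
        if config.layer_norm == "feature_map":
            config = replace(config, seq_len=window_size)
        self.config = config
        self.window_size = window_size
        rng = np.random.default_rng(seed)
        self.blocks: list[CEFBlock] = []
        cin = config.in_channels
        for b in range(config.n_blocks):
            self.blocks.append(CEFBlock(cin, config, rng, name=f"block{b}"))
            cin = config.filters
        self.pool = nn.GlobalAvgPool1d()
        self.head = nn.Linear(config.filters, config.n_classes, rng=rng,
                              name="head")
        self.history: list[float] = []

    def parameters(self) -> list[nn.Parameter]:
        ps = [p for b in self.blocks for p in b.parameters()]
        return ps + self.head.parameters()

    def batchnorms(self):
        from .model import _iter_batchnorms

        return [bn for b in self.blocks for bn in _iter_batchnorms(b)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """``(B, 3, size)`` -> logits ``(B, C)``."""
        for b in self.blocks:
            x = b.forward(x, training)
        return self.head.forward(self.pool.forward(x, training), training)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.pool.backward(self.head.backward(grad))
        for b in reversed(self.blocks):
            grad = b.backward(grad)

    def predict_proba(self, windows: np.ndarray, chunk: int = 256) -> np.ndarray:
        """``(N, 3, size)`` -> softmax probabilities ``(N, C)`` (inference mode)."""
        out = []
        for start in range(0, len(windows), chunk):
            logits = self.forward(windows[start : start + chunk], training=False)
            out.append(nn.softmax(logits, axis=1))
        return np.concatenate(out, axis=0)


def _dataset_windows(
    data: Dataset, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in data:
        for _, frames, labels in segment(s, spec):
            xs.append(frames.T)
            ys.append(window_label(labels))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def train_window_classifier(
    train_data: Dataset,
    spec: WindowSpec,
    model_config: ModelConfig,
    train_config,
    batch_size: int | None = None,
) -> WindowClassifier:
    """Fit the window classifier on (window, majority label) pairs.

    Windows are much shorter than recordings, so the batch size defaults to
    16x the sample-level one.  The per-epoch mean window loss is recorded on
    ``classifier.history``.
    """
    x, y = _dataset_windows(train_data, spec)
    clf = WindowClassifier(model_config, spec.size, seed=train_config.seed)
    opt = nn.Adam(clf.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    bs = batch_size or train_config.batch_size * 16
    n = len(x)
    for _ in range(train_config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            logits = clf.forward(x[idx], training=True)
            loss, dlogits, _ = nn.cross_entropy_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError("non-finite window-classifier loss")
            opt.zero_grad()
            clf.backward(dlogits)
            opt.step()
            total += loss
        clf.history.append(total / n)
    from .training import recalibrate_batchnorms

    recalibrate_batchnorms(clf, x, bs)
    return clf


def predict_sw(
    classifier: WindowClassifier, sample: AccelSample, spec: WindowSpec
) -> np.ndarray:
    """Frame-level prediction by windowed classification + confidence expansion.

    Every window is classified; each covered frame takes the class of its
    most confident covering window (ties -> earlier window); trailing uncovered
    frames inherit the last covered frame's assignment.
    """
    windows = segment(sample, spec)
    starts = [w[0] for w in windows]
    x = np.stack([w[1].T for w in windows])
    probs = classifier.predict_proba(x)
    preds = [
        WindowPrediction(
            start=start,
            size=spec.size,
            class_index=int(p.argmax()),
            confidence=float(p.max()),
        )
        for start, p in zip(starts, probs)
    ]
    T = sample.n_frames
    out = np.full(T, -1, dtype=np.int64)
    best = np.full(T, -np.inf)
    for wp in preds:
        sl = slice(wp.start, wp.start + wp.size)
        take = wp.confidence > best[sl]  # strict: earlier window wins ties
        out[sl][take] = wp.class_index
        best[sl][take] = wp.confidence
    uncovered = out < 0
    if uncovered.any():
        covered_idx = np.flatnonzero(~uncovered)
        for t in np.flatnonzero(uncovered):
            nearest = covered_idx[np.argmin(np.abs(covered_idx - t))]
            out[t] = out[nearest]
    return out
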