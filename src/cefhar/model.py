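"""The classification-every-frame (CEF) network.

Three stacked structures, each a multi-kernel feature-extraction block followed
by channel attention and temporal (dot-product, sigmoid-scored) self-attention,
then a per-frame affine head with softmax — every stage preserves the time
length, so the model emits one class distribution per input frame.

Feature extraction runs five parallel 1-D convolution branches with kernel
widths 5/10/20/50/100 (length-preserving zero padding), each followed by two
width-1 convolutions; branch outputs are concatenated on the channel axis and
fused by a final width-1 convolution.  Every convolution is followed by batch
normalization, layer normalization and ReLU.  Each stacked structure closes
with one further batch-norm + layer-norm pair after the attention stage.

In the canonical configuration (64 filters everywhere, reduction 16, protocol
length 250) the layer normalizations carry an elementwise affine over the whole
(channels x time) feature map, and the network has exactly 3,416,583 learnable
parameters; ``parameter_ledger`` itemizes them.  The per-channel layer-norm
mode keeps the model shape-free in T for variable-length use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "AttentionRecord",
    "FeatureExtractionBlock",
    "CEFBlock",
    "CEFNet",
    "canonical_config",
    "tiny_config",
    "count_parameters",
    "parameter_ledger",
    "predict_frames",
]

CANONICAL_PARAMETER_COUNT = 3_416_583


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``layer_norm`` selects the layer-normalization dialect: ``"feature_map"``
    (affine over channels x time; requires ``seq_len``) or ``"channel"``
    (per-frame, length-free).  ``attention_scale`` enables optional 1/sqrt(F)
    scaling of self-attention scores (off by default).
    """

    kernel_sizes: tuple[int, ...] = (5, 10, 20, 50, 100)
    filters: int = 64
    n_blocks: int = 3
    reduction: int = 16
    in_channels: int = 3
    n_classes: int = 7
    seq_len: int | None = 250
    layer_norm: str = "feature_map"
    attention_scale: bool = False

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if any(k < 1 for k in self.kernel_sizes):
            raise ValueError("all kernel sizes must be >= 1")
        if self.filters % self.reduction != 0:
            raise ValueError(
                f"filters ({self.filters}) must be divisible by the "
                f"channel-attention reduction ({self.reduction})"
            )
        if self.layer_norm not in ("channel", "feature_map"):
            raise ValueError(f"unknown layer_norm mode {self.layer_norm!r}")
        if self.layer_norm == "feature_map" and self.seq_len is None:
            raise ValueError("feature_map layer_norm requires seq_len")


def canonical_config() -> ModelConfig:
    """The full-size configuration whose parameter count is the checksum."""
    return ModelConfig()


def tiny_config(seq_len: int | None = 250,
                layer_norm: str | None = None) -> ModelConfig:
    """Desk-scale preset: 16 filters, one block, reduction 4."""
    if layer_norm is None:
        layer_norm = "feature_map" if seq_len is not None else "channel"
    return ModelConfig(filters=16, n_blocks=1, reduction=4,
                       seq_len=seq_len, layer_norm=layer_norm)


@dataclass
class AttentionRecord:
    """Per-block attention scores from one forward pass (sigmoid outputs in (0,1))."""

    channel_scores: list[np.ndarray] = field(default_factory=list)  # (F,) each
    spatial_scores: list[np.ndarray] = field(default_factory=list)  # (T, T) each


def _conv_unit(cin: int, cout: int, k: int, config: ModelConfig,
               rng: np.random.Generator, name: str,
               use_norms: bool = True) -> nn.Sequential:
    layers: list[nn.Layer] = [
        nn.Conv1d(cin, cout, k, rng=rng, name=f"{name}.conv")
    ]
    if use_norms:
        layers.append(nn.BatchNorm1d(cout, name=f"{name}.bn"))
        layers.append(
            nn.LayerNorm(cout, mode=config.layer_norm, seq_len=config.seq_len,
                         name=f"{name}.ln")
        )
    layers.append(nn.ReLU())
    return nn.Sequential(*layers)


class FeatureExtractionBlock(nn.Layer):
    """Multi-kernel branches -> channel concatenation -> width-1 fusion.

    Each branch: conv(k) -> norms -> ReLU, then two width-1 convs with the same
    norm/activation pattern.  ``use_norms=False`` replaces every normalization
    by the identity (used by brute-force oracle tests)."""

    def __init__(self, in_channels: int, config: ModelConfig,
                 rng: np.random.Generator, name: str = "fe",
                 use_norms: bool = True):
        F = config.filters
        self.branches: list[nn.Sequential] = []
        for k in config.kernel_sizes:
            units = [
                _conv_unit(in_channels, F, k, config, rng,
                           f"{name}.branch_k{k}.0", use_norms)
            ]
            for j in (1, 2):
                units.append(
                    _conv_unit(F, F, 1, config, rng,
                               f"{name}.branch_k{k}.{j}", use_norms)
                )
            self.branches.append(nn.Sequential(*units))
        self.fuse = _conv_unit(len(config.kernel_sizes) * F, F, 1, config, rng,
                               f"{name}.fuse", use_norms)
        self.filters = F

    def parameters(self) -> list[nn.Parameter]:
        ps = [p for b in self.branches for p in b.parameters()]
        return ps + self.fuse.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[2] < 1:
            raise ValueError("input must contain at least one frame")
        outs = [b.forward(x, training) for b in self.branches]
        cat = np.concatenate(outs, axis=1)
        return self.fuse.forward(cat, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dcat = self.fuse.backward(grad)
        F = self.filters
        dx = None
        for i, b in enumerate(self.branches):
            part = b.backward(dcat[:, i * F : (i + 1) * F, :])
            dx = part if dx is None else dx + part
        return dx


class CEFBlock(nn.Layer):
    """One stacked structure: feature extraction + channel/temporal attention."""

    def __init__(self, in_channels: int, config: ModelConfig,
                 rng: np.random.Generator, name: str = "block",
                 use_norms: bool = True):
        F = config.filters
        self.fe = FeatureExtractionBlock(in_channels, config, rng,
                                         name=f"{name}.fe", use_norms=use_norms)
        self.ca = nn.ChannelAttention(F, config.reduction, rng=rng,
                                      name=f"{name}.ca")
        self.sa = nn.SpatialAttention(F, scale=config.attention_scale, rng=rng,
                                      name=f"{name}.sa")
        self.post: list[nn.Layer] = []
        if use_norms:
            self.post = [
                nn.BatchNorm1d(F, name=f"{name}.post.bn"),
                nn.LayerNorm(F, mode=config.layer_norm, seq_len=config.seq_len,
                             name=f"{name}.post.ln"),
            ]

    def parameters(self) -> list[nn.Parameter]:
        ps = self.fe.parameters() + self.ca.parameters() + self.sa.parameters()
        return ps + [p for l in self.post for p in l.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = self.fe.forward(x, training)
        y = self.ca.forward(y, training)
        y = self.sa.forward(y, training)
        for l in self.post:
            y = l.forward(y, training)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.post):
            grad = l.backward(grad)
        grad = self.sa.backward(grad)
        grad = self.ca.backward(grad)
        return self.fe.backward(grad)


class CEFNet:
    """The full per-frame classifier: stacked blocks + width-1 affine head."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 use_norms: bool = True):
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[CEFBlock] = []
        cin = config.in_channels
        for b in range(config.n_blocks):
            self.blocks.append(
                CEFBlock(cin, config, rng, name=f"block{b}", use_norms=use_norms)
            )
            cin = config.filters
        self.head = nn.Conv1d(config.filters, config.n_classes, 1, rng=rng,
                              name="head")

    def parameters(self) -> list[nn.Parameter]:
        ps = [p for b in self.blocks for p in b.parameters()]
        return ps + self.head.parameters()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Batch forward: ``(B, 3, T)`` -> logits ``(B, C, T)``."""
        if not np.isfinite(x).all():
            raise ValueError("input contains non-finite values")
        for b in self.blocks:
            x = b.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        for b in reversed(self.blocks):
            grad = b.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def batchnorms(self) -> list[nn.BatchNorm1d]:
        return [bn for b in self.blocks for bn in _iter_batchnorms(b)]

    def attention_record(self) -> AttentionRecord:
        """Attention scores from the most recent forward pass (batch element 0)."""
        rec = AttentionRecord()
        for b in self.blocks:
            rec.channel_scores.append(b.ca.scores[0].copy())
            rec.spatial_scores.append(b.sa.scores[0].copy())
        return rec

    def forward_sample(
        self, frames: np.ndarray
    ) -> tuple[np.ndarray, AttentionRecord]:
        """Classify one recording: ``(T, 3)`` -> per-frame probabilities ``(T, C)``.

        Also returns the attention record of the pass.  Deterministic given the
        model's weights (inference mode)."""
        frames = np.asarray(frames, dtype=np.float64)
        if frames.ndim != 2 or frames.shape[1] != self.config.in_channels:
            raise ValueError(
                f"frames must have shape (T, {self.config.in_channels})"
            )
        logits = self.forward(frames.T[None, :, :], training=False)
        probs = nn.softmax(logits, axis=1)[0].T
        return probs, self.attention_record()

    # --- weight (de)serialization -----------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.parameters()}
        for i, b in enumerate(self.blocks):
            state.update(_norm_running_state(b, f"block{i}"))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data[...] = state[p.name]
        for i, b in enumerate(self.blocks):
            _load_norm_running_state(b, f"block{i}", state)


def _iter_batchnorms(block: CEFBlock):
    for br in block.fe.branches:
        for seq in br.layers:
            for l in seq.layers:
                if isinstance(l, nn.BatchNorm1d):
                    yield l
    for l in block.fe.fuse.layers:
        if isinstance(l, nn.BatchNorm1d):
            yield l
    for l in block.post:
        if isinstance(l, nn.BatchNorm1d):
            yield l


def _norm_running_state(block: CEFBlock, prefix: str) -> dict[str, np.ndarray]:
    out = {}
    for j, bn in enumerate(_iter_batchnorms(block)):
        out[f"{prefix}._running.{j}.mean"] = bn.running_mean.copy()
        out[f"{prefix}._running.{j}.var"] = bn.running_var.copy()
    return out


def _load_norm_running_state(block: CEFBlock, prefix: str,
                             state: dict[str, np.ndarray]) -> None:
    for j, bn in enumerate(_iter_batchnorms(block)):
        key = f"{prefix}._running.{j}"
        if f"{key}.mean" in state:
            bn.running_mean[...] = state[f"{key}.mean"]
            bn.running_var[...] = state[f"{key}.var"]


def count_parameters(config: ModelConfig) -> int:
    """Number of learnable scalars of the network ``CEFNet(config)`` builds."""
    return CEFNet(config).n_parameters()


def parameter_ledger(config: ModelConfig) -> list[tuple[str, int]]:
    """Per-container (name, size) itemization of every learnable array."""
    return [(p.name, p.size) for p in CEFNet(config).parameters()]


def save_checkpoint(model: CEFNet, path, seed: int | None = None) -> None:
    """Write weights + configuration (+ optional seed provenance) to an .npz file."""
    import dataclasses
    import json

    meta = {"config": dataclasses.asdict(model.config), "seed": seed,
            "format": "cefhar-ckpt-v1"}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> CEFNet:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format") != "cefhar-ckpt-v1":
            raise ValueError(f"{path}: not a cefhar checkpoint")
        cfg = meta["config"]
        cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
        config = ModelConfig(**cfg)
        model = CEFNet(config, seed=meta.get("seed") or 0)
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model.load_state_dict(state)
    return model


def predict_frames(probs: np.ndarray) -> np.ndarray:
    """Per-frame argmax of a ``(T, C)`` probability matrix; ties -> lowest index."""
    probs = np.asarray(probs)
    if probs.ndim != 2:
        raise ValueError("probs must be a (T, C) matrix")
    return probs.argmax(axis=1)
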