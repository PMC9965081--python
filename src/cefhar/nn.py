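"""A compact numpy layer library with explicit backward passes.

All sequence layers operate on channels-first arrays of shape ``(B, C, T)``
(batch, channels, time) in float64.  Every layer caches what its backward pass
needs on the most recent forward call; the training loop is single-threaded and
calls forward/backward strictly in pairs.  Gradients of every layer are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Sequential",
    "Conv1d",
    "BatchNorm1d",
    "LayerNorm",
    "ReLU",
    "GlobalAvgPool1d",
    "Linear",
    "ChannelAttention",
    "SpatialAttention",
    "softmax",
    "cross_entropy_logits",
    "Adam",
]


class Parameter:
    """A named learnable array with an accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: parameters(), forward(x, training), backward(grad)."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """Length-preserving 1-D convolution (cross-correlation).

    Even kernel widths cannot pad symmetrically; we zero-pad ``(k-1)//2`` frames
    on the left and the remainder on the right, so the output always has the
    input's time length.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            f"{name}.weight",
            _uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in),
        )
        self.bias = (
            Parameter(f"{name}.bias", _uniform_init(rng, (out_channels,), fan_in))
            if bias
            else None
        )
        self.pad_left = (kernel_size - 1) // 2
        self.pad_right = kernel_size - 1 - self.pad_left
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    # Two equivalent execution paths: a loop over kernel taps (cheap for long
    # sequences, no large intermediate) and an im2col matmul (much faster for
    # short sequences such as sliding windows, at the cost of a (B, T, C*k)
    # buffer).  The im2col path is taken when that buffer stays small.
    _IM2COL_MAX_ELEMS = 4_000_000

    def _use_im2col(self, B: int, T: int) -> bool:
        k = self.kernel_size
        return k > 1 and B * T * self.in_channels * k <= self._IM2COL_MAX_ELEMS

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        B, C, T = x.shape
        k = self.kernel_size
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        W = self.weight.data
        if self._use_im2col(B, T):
            from numpy.lib.stride_tricks import sliding_window_view

            cols = sliding_window_view(xp, k, axis=2)  # (B, C, T, k) view
            cm = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
                B * T, C * k
            )
            y = (cm @ W.reshape(self.out_channels, C * k).T).reshape(
                B, T, self.out_channels
            )
            y = np.ascontiguousarray(y.transpose(0, 2, 1))
            self._cm = cm
        else:
            y = np.zeros((B, self.out_channels, T))
            for j in range(k):
                # y[b,o,t] += sum_c W[o,c,j] * xp[b,c,t+j]
                y += np.einsum("oc,bct->bot", W[:, :, j], xp[:, :, j : j + T])
            self._cm = None
        if self.bias is not None:
            y += self.bias.data[None, :, None]
        self._xp = xp
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, C, _ = xp.shape
        T = grad.shape[2]
        k = self.kernel_size
        O = self.out_channels
        W = self.weight.data
        dxp = np.zeros_like(xp)
        if self._cm is not None:
            g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(B * T, O)
            self.weight.grad += (g2.T @ self._cm).reshape(O, C, k)
            dcols = (g2 @ W.reshape(O, C * k)).reshape(B, T, C, k)
            dcols = dcols.transpose(0, 2, 1, 3)  # (B, C, T, k)
            for j in range(k):
                dxp[:, :, j : j + T] += dcols[:, :, :, j]
        else:
            for j in range(k):
                self.weight.grad[:, :, j] += np.einsum(
                    "bot,bct->oc", grad, xp[:, :, j : j + T]
                )
                dxp[:, :, j : j + T] += np.einsum("oc,bot->bct", W[:, :, j], grad)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        return dxp[:, :, self.pad_left : self.pad_left + T]


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(f"{name}.weight", np.ones(channels))
        self.bias = Parameter(f"{name}.bias", np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.weight.data[None, :, None] * xhat + self.bias.data[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        g = self.weight.data[None, :, None]
        self.weight.grad += (grad * xhat).sum(axis=(0, 2))
        self.bias.grad += grad.sum(axis=(0, 2))
        dxhat = grad * g
        if not training:
            return dxhat * inv[None, :, None]
        B, _, T = shape
        n = B * T
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv[None, :, None] / n) * (n * dxhat - s1 - xhat * s2)


class LayerNorm(Layer):
    """Layer normalization in one of two modes.

    ``"channel"``
        statistics and affine over the channel axis, independently per frame;
        shape-free in T (2C parameters).
    ``"feature_map"``
        statistics and elementwise affine over the whole (C, T) feature map of
        each sample (2CT parameters); the canonical protocol-length dialect,
        which ties the layer to a fixed sequence length.
    """

    def __init__(self, channels: int, mode: str = "channel",
                 seq_len: int | None = None, eps: float = 1e-5, name: str = "ln"):
        if mode not in ("channel", "feature_map"):
            raise ValueError(f"unknown LayerNorm mode {mode!r}")
        if mode == "feature_map" and seq_len is None:
            raise ValueError("feature_map mode requires seq_len")
        self.mode = mode
        self.channels = channels
        self.seq_len = seq_len
        self.eps = eps
        shape = (channels,) if mode == "channel" else (channels, seq_len)
        self.weight = Parameter(f"{name}.weight", np.ones(shape))
        self.bias = Parameter(f"{name}.bias", np.zeros(shape))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _axes(self):
        return (1,) if self.mode == "channel" else (1, 2)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.mode == "feature_map" and x.shape[2] != self.seq_len:
            raise ValueError(
                f"feature_map LayerNorm built for T={self.seq_len}, "
                f"got T={x.shape[2]}"
            )
        axes = self._axes()
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        w = self.weight.data
        b = self.bias.data
        if self.mode == "channel":
            w, b = w[None, :, None], b[None, :, None]
        else:
            w, b = w[None, :, :], b[None, :, :]
        return w * xhat + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = self._axes()
        if self.mode == "channel":
            self.weight.grad += (grad * xhat).sum(axis=(0, 2))
            self.bias.grad += grad.sum(axis=(0, 2))
            w = self.weight.data[None, :, None]
        else:
            self.weight.grad += (grad * xhat).sum(axis=0)
            self.bias.grad += grad.sum(axis=0)
            w = self.weight.data[None, :, :]
        dxhat = grad * w
        n = np.prod([xhat.shape[a] for a in axes])
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (inv / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class GlobalAvgPool1d(Layer):
    """(B, C, T) -> (B, C) mean over the time axis."""

    def __init__(self):
        self._T = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._T, axis=2) / self._T


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            f"{name}.weight", _uniform_init(rng, (out_features, in_features), in_features)
        )
        self.bias = (
            Parameter(f"{name}.bias", _uniform_init(rng, (out_features,), in_features))
            if bias
            else None
        )
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y = y + self.bias.data[None, :]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class ChannelAttention(Layer):
    """CBAM-style channel gate from time-pooled descriptors.

    Average- and max-pooled channel descriptors pass through the *same*
    two-layer bottleneck (F -> F/r, ReLU, F/r -> F; the first projection is
    bias-free), the two maps are added elementwise, and a sigmoid yields one
    gating score per channel, which rescales the input.  The last forward's
    scores are kept on ``self.scores`` for inspection.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None, name: str = "ca"):
        if channels % reduction != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})"
            )
        rng = rng or np.random.default_rng(0)
        hidden = channels // reduction
        self.channels = channels
        self.w1 = Parameter(f"{name}.fc1.weight", _uniform_init(rng, (hidden, channels), channels))
        self.w2 = Parameter(f"{name}.fc2.weight", _uniform_init(rng, (channels, hidden), hidden))
        self.b2 = Parameter(f"{name}.fc2.bias", _uniform_init(rng, (channels,), hidden))
        self.scores: np.ndarray | None = None
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.w1, self.w2, self.b2]

    def _mlp(self, v: np.ndarray):
        h = v @ self.w1.data.T
        hr = np.maximum(h, 0.0)
        return hr @ self.w2.data.T + self.b2.data[None, :], (v, h, hr)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        avg = x.mean(axis=2)
        idx = x.argmax(axis=2)
        mx = np.take_along_axis(x, idx[:, :, None], axis=2)[:, :, 0]
        o_avg, c_avg = self._mlp(avg)
        o_max, c_max = self._mlp(mx)
        s = _sigmoid(o_avg + o_max)
        self.scores = s
        self._cache = (x, s, c_avg, c_max, idx)
        return x * s[:, :, None]

    def _mlp_backward(self, dout: np.ndarray, cache) -> np.ndarray:
        v, h, hr = cache
        self.w2.grad += dout.T @ hr
        self.b2.grad += dout.sum(axis=0)
        dh = (dout @ self.w2.data) * (h > 0)
        self.w1.grad += dh.T @ v
        return dh @ self.w1.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s, c_avg, c_max, idx = self._cache
        B, C, T = x.shape
        dx = grad * s[:, :, None]
        ds = (grad * x).sum(axis=2)
        dpre = ds * s * (1.0 - s)
        dv_avg = self._mlp_backward(dpre, c_avg)
        dv_max = self._mlp_backward(dpre, c_max)
        dx += dv_avg[:, :, None] / T
        bi, ci = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        np.add.at(dx, (bi, ci, idx), dv_max)
        return dx


class SpatialAttention(Layer):
    """Dot-product temporal self-attention with a sigmoid score map.

    Query, key and value are produced by three distinct width-1 convolutions;
    the raw T x T map is Q^T K, squashed *elementwise by a sigmoid* (not a
    softmax), and applied to the value: y[:, t] = sum_s S[t, s] V[:, s].  No
    pooling touches the time axis, so positional information survives.  Score
    scaling by 1/sqrt(F) is available behind a flag and off by default.
    """

    def __init__(self, channels: int, scale: bool = False,
                 rng: np.random.Generator | None = None, name: str = "sa"):
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.scale = scale
        def proj(tag):
            return (
                Parameter(f"{name}.{tag}.weight", _uniform_init(rng, (channels, channels), channels)),
                Parameter(f"{name}.{tag}.bias", _uniform_init(rng, (channels,), channels)),
            )
        self.wq, self.bq = proj("query")
        self.wk, self.bk = proj("key")
        self.wv, self.bv = proj("value")
        self.scores: np.ndarray | None = None
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.wq, self.bq, self.wk, self.bk, self.wv, self.bv]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        Q = np.einsum("oc,bct->bot", self.wq.data, x) + self.bq.data[None, :, None]
        K = np.einsum("oc,bct->bot", self.wk.data, x) + self.bk.data[None, :, None]
        V = np.einsum("oc,bct->bot", self.wv.data, x) + self.bv.data[None, :, None]
        A = np.einsum("bct,bcs->bts", Q, K)
        if self.scale:
            A = A / np.sqrt(self.channels)
        S = _sigmoid(A)
        y = np.einsum("bcs,bts->bct", V, S)
        self.scores = S
        self._cache = (x, Q, K, V, S)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, Q, K, V, S = self._cache
        dV = np.einsum("bct,bts->bcs", grad, S)
        dS = np.einsum("bct,bcs->bts", grad, V)
        dA = dS * S * (1.0 - S)
        if self.scale:
            dA = dA / np.sqrt(self.channels)
        dQ = np.einsum("bts,bcs->bct", dA, K)
        dK = np.einsum("bts,bct->bcs", dA, Q)
        dx = np.zeros_like(x)
        for W, b, dP in ((self.wq, self.bq, dQ), (self.wk, self.bk, dK),
                         (self.wv, self.bv, dV)):
            W.grad += np.einsum("bot,bct->oc", dP, x)
            b.grad += dP.sum(axis=(0, 2))
            dx += np.einsum("oc,bot->bct", W.data, dP)
        return dx


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Summed (not averaged) cross-entropy from logits.

    ``logits`` is ``(B, C, T)`` with integer ``labels`` of shape ``(B, T)``, or
    ``(B, C)`` with labels ``(B,)``.  Returns (loss, dloss/dlogits, probs); the
    loss is the sum over all frames and batch elements, matching the per-frame
    summed objective.
    """
    squeeze = logits.ndim == 2
    if squeeze:
        logits = logits[:, :, None]
        labels = labels[:, None]
    if logits.shape[0] != labels.shape[0] or logits.shape[2] != labels.shape[1]:
        raise ValueError("logits and labels shapes do not match")
    probs = softmax(logits, axis=1)
    B, C, T = logits.shape
    bi = np.arange(B)[:, None]
    ti = np.arange(T)[None, :]
    p_true = probs[bi, labels, ti]
    loss = float(-np.log(np.clip(p_true, 1e-300, None)).sum())
    grad = probs.copy()
    np.subtract.at(grad, (bi, labels, ti), 1.0)
    if squeeze:
        return loss, grad[:, :, 0], probs[:, :, 0]
    return loss, grad, probs


class Adam:
    """Adam with bias correction; operates in place on a parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
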