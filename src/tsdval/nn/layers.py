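"""Neural-network building blocks on top of the autodiff engine.

Layers hold their parameters as :class:`Tensor` objects with
``requires_grad=True``; :class:`Module` collects them recursively.  All
randomness (initialization, dropout masks) flows through an explicit
``numpy.random.Generator`` so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, matmul

__all__ = [
    "Module", "Dense", "Conv1D", "LayerNorm", "Dropout",
    "MultiHeadSelfAttention", "TransformerEncoderBlock", "GRU",
    "global_average_pool", "global_max_pool", "max_pool1d",
    "sinusoidal_position_encoding",
]


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # single-file checkpointing -------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model has {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


_ACTIVATIONS = {
    None: lambda t: t,
    "linear": lambda t: t,
    "relu": Tensor.relu,
    "gelu": Tensor.gelu,
    "tanh": Tensor.tanh,
    "sigmoid": Tensor.sigmoid,
}


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.w = Tensor(_glorot(rng, in_features, out_features,
                                (in_features, out_features)), requires_grad=True)
        self.b = Tensor(np.zeros(out_features), requires_grad=True)
        self.activation = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        return self.activation(matmul(x, self.w) + self.b)


class Conv1D(Module):
    """1-D convolution over (batch, time, channels) with 'same' zero padding."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, activation: str | None = None):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.kernel = kernel
        self.in_channels = in_channels
        self.w = Tensor(_glorot(rng, kernel * in_channels, filters,
                                (kernel * in_channels, filters)), requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)
        self.activation = _ACTIVATIONS[activation]

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[2] != self.in_channels:
            raise ValueError(
                f"expected input (B, L, {self.in_channels}), got {x.shape}")
        length = x.shape[1]
        if length < self.kernel:
            raise ValueError(f"input length {length} < kernel {self.kernel}")
        before = (self.kernel - 1) // 2
        after = self.kernel - 1 - before
        xp = x.pad_axis(1, before, after) if self.kernel > 1 else x
        idx = np.arange(length)[:, None] + np.arange(self.kernel)[None, :]
        patches = xp[:, idx, :]                      # (B, L, k, Cin)
        flat = patches.reshape(x.shape[0], length, self.kernel * self.in_channels)
        return self.activation(matmul(flat, self.w) + self.b)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode or when rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng)
        self.wk = Dense(d_model, d_model, rng)
        self.wv = Dense(d_model, d_model, rng)
        self.wo = Dense(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, length, d = x.shape

        def split(t: Tensor) -> Tensor:  # (B, L, D) -> (B, H, L, dh)
            return t.reshape(b, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)
        ctx = matmul(attn, v).transpose(0, 2, 1, 3).reshape(b, length, d)
        return self.wo(ctx)


class TransformerEncoderBlock(Module):
    """Post-norm encoder block: MHSA + residual + LN, FFN + residual + LN."""

    def __init__(self, d_model: int, n_heads: int, ffn_units: int,
                 dropout: float, rng: np.random.Generator,
                 activation: str = "gelu"):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ffn1 = Dense(d_model, ffn_units, rng, activation=activation)
        self.ffn2 = Dense(ffn_units, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x)))
        return self.ln2(x + self.drop2(self.ffn2(self.ffn1(x))))


class GRU(Module):
    """Gated recurrent unit over (batch, time, channels); returns last hidden state."""

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        self.units = units
        d = in_features
        self.wz = Tensor(_glorot(rng, d + units, units, (d + units, units)),
                         requires_grad=True)
        self.bz = Tensor(np.zeros(units), requires_grad=True)
        self.wr = Tensor(_glorot(rng, d + units, units, (d + units, units)),
                         requires_grad=True)
        self.br = Tensor(np.zeros(units), requires_grad=True)
        self.wh = Tensor(_glorot(rng, d + units, units, (d + units, units)),
                         requires_grad=True)
        self.bh = Tensor(np.zeros(units), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        b, length, _ = x.shape
        h = Tensor(np.zeros((b, self.units)))
        for t in range(length):
            xt = x[:, t, :]
            xh = concat([xt, h], axis=-1)
            z = (matmul(xh, self.wz) + self.bz).sigmoid()
            r = (matmul(xh, self.wr) + self.br).sigmoid()
            xrh = concat([xt, r * h], axis=-1)
            h_tilde = (matmul(xrh, self.wh) + self.bh).tanh()
            h = (1.0 - z) * h + z * h_tilde
        return h


def max_pool1d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping temporal max pooling; trailing remainder is dropped."""
    b, length, c = x.shape
    usable = (length // size) * size
    if usable == 0:
        raise ValueError(f"input length {length} shorter than pool size {size}")
    if usable != length:
        x = x[:, :usable, :]
    return x.reshape(b, usable // size, size, c).max(axis=2)


def global_average_pool(x: Tensor) -> Tensor:
    return x.mean(axis=1)


def global_max_pool(x: Tensor) -> Tensor:
    return x.max(axis=1)


def sinusoidal_position_encoding(length: int, d_model: int) -> np.ndarray:
    """Standard fixed sin/cos positional encoding, shape (length, d_model)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.empty((length, d_model))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc
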