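"""The data value estimator (DVE).

Maps a raw window, its label and per-class marginal information to a
selection probability h(x, y) in (0, 1) — the sample's value.  The network:

* feature extractor: one 1D convolution (64 filters, kernel 3, GeLU) followed
  by two structurally identical transformer encoder blocks (2 heads,
  feed-forward width 256, dropout 0.1, GeLU) and global average pooling over
  time, so both local and global temporal structure of the multichannel
  window reach the embedding;
* conditioning: the embedding is concatenated with the one-hot label and
  refined by five dense layers of 100 ReLU units;
* the marginal information m(x, y) = |y_onehot - f_v(x)| — a per-class
  contamination signal from a validation-pretrained predictor — is
  concatenated *after* the MLP, so it reaches the output only through the
  final dense layer;
* a final dense layer squashed by a sigmoid yields the probability, clipped
  to [1e-6, 1 - 1e-6] so the Bernoulli log-likelihood stays finite.

``selection_logprob`` is the log-probability of a binary selection vector
under independent Bernoulli draws with these probabilities — the policy term
of the REINFORCE update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Adam, Conv1D, Dense, Module, Tensor,
                 TransformerEncoderBlock, concat, global_average_pool,
                 sinusoidal_position_encoding)

__all__ = ["DVEConfig", "DataValueEstimator", "selection_logprob", "PROB_CLIP"]

# Clipping bound keeping log p and log(1-p) finite in the REINFORCE surrogate.
PROB_CLIP = 1e-6


@dataclass(frozen=True)
class DVEConfig:
    conv_filters: int = 64
    conv_kernel: int = 3
    n_transformer_blocks: int = 2
    n_heads: int = 2
    ffn_units: int = 256
    dropout: float = 0.1
    mlp_layers: int = 5
    mlp_units: int = 100

    def validate(self) -> None:
        for name in ("conv_filters", "conv_kernel", "n_transformer_blocks",
                     "n_heads", "ffn_units", "mlp_layers", "mlp_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class DataValueEstimator(Module):
    def __init__(self, window_len: int, n_channels: int, n_classes: int,
                 cfg: DVEConfig | None = None, *, seed: int = 0):
        cfg = cfg or DVEConfig()
        cfg.validate()
        if window_len < cfg.conv_kernel:
            raise ValueError("window_len must be >= conv_kernel")
        self.cfg = cfg
        self.window_len = window_len
        self.n_channels = n_channels
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)

        self.conv = Conv1D(n_channels, cfg.conv_filters, cfg.conv_kernel, rng,
                           activation="gelu")
        self._pos = sinusoidal_position_encoding(window_len, cfg.conv_filters)
        self.blocks = [
            TransformerEncoderBlock(cfg.conv_filters, cfg.n_heads,
                                    cfg.ffn_units, cfg.dropout, rng)
            for _ in range(cfg.n_transformer_blocks)
        ]
        self.mlp = [
            Dense(cfg.conv_filters + n_classes if i == 0 else cfg.mlp_units,
                  cfg.mlp_units, rng, activation="relu")
            for i in range(cfg.mlp_layers)
        ]
        # Zero-initialized head: every sample starts at value exactly 0.5, so
        # the initial value ordering carries no random bias from the head
        # weights; gradients still flow since the head inputs are nonzero.
        self.out = Dense(cfg.mlp_units + n_classes, 1, rng)
        self.out.w.data[:] = 0.0
        self.out.b.data[:] = 0.0

    # -- pieces ---------------------------------------------------------------
    def extract_features(self, x: Tensor | np.ndarray) -> Tensor:
        """Embed a batch of windows: (B, W, C) -> (B, conv_filters)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 3 or x.shape[1] != self.window_len \
                or x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected (B, {self.window_len}, {self.n_channels}), got {x.shape}")
        h = self.conv(x) + Tensor(self._pos)
        for block in self.blocks:
            h = block(h)
        return global_average_pool(h)

    def selection_probability(self, x, y_onehot: np.ndarray,
                              marginal: np.ndarray) -> Tensor:
        """Per-sample selection probability, shape (B,), clipped to (0, 1)."""
        y_onehot = np.asarray(y_onehot, dtype=np.float64)
        marginal = np.asarray(marginal, dtype=np.float64)
        if y_onehot.ndim != 2 or y_onehot.shape[1] != self.n_classes:
            raise ValueError("y_onehot must be (B, K)")
        if not (np.isin(y_onehot, (0.0, 1.0)).all()
                and (y_onehot.sum(axis=1) == 1.0).all()):
            raise ValueError("y_onehot rows must be one-hot")
        if marginal.shape != y_onehot.shape:
            raise ValueError("marginal must be (B, K), aligned with labels")
        emb = self.extract_features(x)
        h = concat([emb, Tensor(y_onehot)], axis=-1)
        for layer in self.mlp:
            h = layer(h)
        z = concat([h, Tensor(marginal)], axis=-1)
        logit = self.out(z).reshape(-1)
        return logit.sigmoid().clip(PROB_CLIP, 1.0 - PROB_CLIP)

    # convenient alias
    __call__ = selection_probability

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.parameters(), lr=lr)


def selection_logprob(probs: Tensor | np.ndarray, s: np.ndarray) -> Tensor:
    """log pi(s) = sum_i [ s_i log p_i + (1 - s_i) log(1 - p_i) ].

    The exponential equals the product of independent Bernoulli likelihoods.
    Probabilities must already be clipped away from {0, 1}.
    """
    p = probs if isinstance(probs, Tensor) else Tensor(probs)
    s = np.asarray(s, dtype=np.float64)
    if s.shape != p.shape:
        raise ValueError("selection vector must align with probabilities")
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("selection vector must be binary")
    if ((p.data <= 0.0) | (p.data >= 1.0)).any():
        raise ValueError("probabilities must lie strictly in (0, 1); clip upstream")
    s_t = Tensor(s)
    return (s_t * p.log() + (1.0 - s_t) * (1.0 - p).log()).sum()
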