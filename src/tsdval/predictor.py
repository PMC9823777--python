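"""The task predictor f_theta and the validation-pretrained predictor f_v.

A double-head 1D-CNN stacking ensemble: two parallel convolutional heads
(64 filters each, kernel sizes 1 and 3, ReLU) look at the same window at
different receptive fields, each is pooled over time (global max), the two
64-vectors are concatenated and a dense softmax classifier sits on top.

Training minimizes the value-weighted cross-entropy

    (1/B) * sum_i  w_i * CE(f(x_i), y_i)

with Adam (lr 0.01 by default); with uniform weights this reduces exactly to
plain cross-entropy training.  ``pretrain_validation_predictor`` fits the
same architecture on the clean validation split only; frozen, it supplies the
marginal information m(x, y) = |y_onehot - f_v(x)| consumed by the value
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import WindowedDataset
from .nn import (Adam, Conv1D, Dense, Module, Tensor, concat,
                 global_max_pool, no_grad)

__all__ = ["PredictorConfig", "DoubleHeadPredictor", "weighted_cross_entropy",
           "fit_weighted", "pretrain_validation_predictor",
           "marginal_information"]


@dataclass(frozen=True)
class PredictorConfig:
    filters: int = 64
    head_kernels: tuple[int, int] = (1, 3)
    dense_units: int = 0          # 0 = softmax classifier directly on the pooled features
    n_classes: int = 3
    lr: float = 0.01
    batch: int = 64
    iterations: int = 200

    def validate(self) -> None:
        if len(self.head_kernels) != 2 or self.head_kernels[0] == self.head_kernels[1]:
            raise ValueError("head_kernels must be two distinct kernel sizes")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.filters < 1 or self.batch < 1 or self.iterations < 0:
            raise ValueError("filters/batch must be positive, iterations >= 0")


class DoubleHeadPredictor(Module):
    def __init__(self, window_len: int, n_channels: int,
                 cfg: PredictorConfig | None = None, *, seed: int = 0):
        cfg = cfg or PredictorConfig()
        cfg.validate()
        self.cfg = cfg
        self.window_len = window_len
        self.n_channels = n_channels
        rng = np.random.default_rng(seed)
        k1, k2 = cfg.head_kernels
        self.head1 = Conv1D(n_channels, cfg.filters, k1, rng, activation="relu")
        self.head2 = Conv1D(n_channels, cfg.filters, k2, rng, activation="relu")
        feat = 2 * cfg.filters
        if cfg.dense_units > 0:
            self.hidden = Dense(feat, cfg.dense_units, rng, activation="relu")
            feat = cfg.dense_units
        else:
            self.hidden = None
        self.classifier = Dense(feat, cfg.n_classes, rng)

    def logits(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 3 or x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected (B, W, {self.n_channels}), got {x.shape}")
        h = concat([global_max_pool(self.head1(x)),
                    global_max_pool(self.head2(x))], axis=-1)
        if self.hidden is not None:
            h = self.hidden(h)
        return self.classifier(h)

    def forward(self, x) -> Tensor:
        """Class-probability matrix (B, K); rows sum to 1."""
        return self.logits(x).softmax(axis=-1)

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.forward(x).data.argmax(axis=1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        with no_grad():
            return self.forward(x).data

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(x) == np.asarray(y)).mean())

    def make_optimizer(self) -> Adam:
        return Adam(self.parameters(), lr=self.cfg.lr)


def weighted_cross_entropy(model: DoubleHeadPredictor, x: np.ndarray,
                           y: np.ndarray, weights: np.ndarray | None) -> Tensor:
    """(1/B) * sum_i w_i * CE_i; ``weights=None`` means uniform weights 1."""
    log_p = model.logits(x).log_softmax(axis=-1)
    b = log_p.shape[0]
    y = np.asarray(y, dtype=np.int64)
    picked = log_p[np.arange(b), y]          # (B,) log-probability of true class
    ce = -picked
    if weights is not None:
        ce = ce * Tensor(np.asarray(weights, dtype=np.float64))
    return ce.mean()


def fit_weighted(ds: WindowedDataset, weights: np.ndarray | None,
                 cfg: PredictorConfig | None = None, *, seed: int = 0,
                 model: DoubleHeadPredictor | None = None,
                 optimizer: Adam | None = None) -> DoubleHeadPredictor:
    """Train the predictor on the training split with per-sample weights.

    Weights may be the value estimator's probabilities, a binary selection
    mask, or ``None`` for plain cross-entropy.  Mini-batches of ``cfg.batch``
    are drawn with a generator seeded from ``seed``; samples with weight 0
    contribute exactly zero gradient.
    """
    x_train, y_train = ds.subset("train")
    n = x_train.shape[0]
    if n == 0:
        raise ValueError("training split is empty")
    if weights is not None:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (n,):
            raise ValueError(f"weights must have shape ({n},)")
        if (weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not weights.any():
            raise ValueError("empty effective training set: all weights are zero")

    cfg = cfg or PredictorConfig(n_classes=ds.n_classes)
    if model is None:
        model = DoubleHeadPredictor(ds.window_len, ds.n_channels, cfg, seed=seed)
    optimizer = optimizer or model.make_optimizer()
    rng = np.random.default_rng(seed)
    batch = min(cfg.batch, n)
    for _ in range(cfg.iterations):
        idx = rng.choice(n, size=batch, replace=False)
        loss = weighted_cross_entropy(model, x_train[idx], y_train[idx],
                                      None if weights is None else weights[idx])
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    return model


def pretrain_validation_predictor(ds: WindowedDataset,
                                  cfg: PredictorConfig | None = None, *,
                                  seed: int = 0) -> DoubleHeadPredictor:
    """Fit f_v on the (clean) validation split only; freeze and return it."""
    x_val, y_val = ds.subset("val")
    if x_val.shape[0] == 0:
        raise ValueError("validation split is empty")
    cfg = cfg or PredictorConfig(n_classes=ds.n_classes)
    model = DoubleHeadPredictor(ds.window_len, ds.n_channels, cfg, seed=seed)
    optimizer = model.make_optimizer()
    rng = np.random.default_rng(seed)
    n = x_val.shape[0]
    batch = min(cfg.batch, n)
    for _ in range(cfg.iterations):
        idx = rng.choice(n, size=batch, replace=False)
        loss = weighted_cross_entropy(model, x_val[idx], y_val[idx], None)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    model.eval()
    return model


def marginal_information(f_v: DoubleHeadPredictor, x: np.ndarray,
                         y: np.ndarray, n_classes: int) -> np.ndarray:
    """m(x, y) = |y_onehot - f_v(x)| per class; each component in [0, 1].

    Small for samples whose label agrees with the validation-pretrained
    predictor, close to 1 in the components a flipped label disagrees on.
    """
    y = np.asarray(y, dtype=np.int64)
    onehot = np.zeros((y.size, n_classes))
    onehot[np.arange(y.size), y] = 1.0
    return np.abs(onehot - f_v.predict_proba(x))
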