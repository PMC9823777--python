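"""Evaluation statistics for a trained valuation: CSD and RHLVS.

Corrupted-sample discovery (CSD): sort training samples ascending by value
and accumulate the lowest v*r of them, where v is 5 % of the training set and
r = 0..10; CSD_r is the fraction of the o injected label flips found in that
accumulation.  The ideal ("optimal") curve is min(v*r / o, 1).

Remove high/low-value samples (RHLVS): for each r, retrain a reference
classifier from scratch on the training split minus the v*r highest-valued
(resp. lowest-valued) samples, weighting each remaining sample by its value,
and record test accuracy.  A good valuation makes accuracy collapse when
high-value data are removed and hold (or improve) when low-value data are.

Three reference classifier variants are provided, all built from two
conv/maxpool blocks (64 filters, kernel 3, ReLU, pool 2): a GRU(8) head with
50 % dropout (clinical-data profile), a plain dense head (public baseline)
and a GRU(8) head with 70 % dropout (public complex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CorruptionRecord, ValueTable, WindowedDataset
from .nn import (Adam, Conv1D, Dense, Dropout, GRU, Module, Tensor,
                 max_pool1d, no_grad)

__all__ = ["CSDCurve", "RHLVSCurve", "ClassifierSpec", "ReferenceClassifier",
           "build_classifier", "csd", "rhlvs"]

_VARIANTS = ("bbs_model", "public_baseline", "public_complex")


@dataclass
class CSDCurve:
    removal_fractions: np.ndarray   # (n_steps + 1,) in [0, 0.5] by default
    discovery: np.ndarray           # fraction of corrupted samples found
    optimal: np.ndarray             # ideal curve min(v r / o, 1)

    @property
    def max_discovery(self) -> float:
        return float(self.discovery.max())

    @property
    def fraction_at_max(self) -> float:
        return float(self.removal_fractions[int(self.discovery.argmax())])


@dataclass
class RHLVSCurve:
    removal_fractions: np.ndarray
    remove_high_acc: np.ndarray
    remove_low_acc: np.ndarray
    classifier_name: str

    @property
    def max_accuracy(self) -> float:
        return float(self.remove_low_acc.max())

    @property
    def improved_accuracy(self) -> float:
        """Best gain over the no-removal accuracy from removing low-value data."""
        return float(self.remove_low_acc.max() - self.remove_low_acc[0])

    @property
    def fraction_at_max(self) -> float:
        return float(self.removal_fractions[int(self.remove_low_acc.argmax())])


@dataclass(frozen=True)
class ClassifierSpec:
    variant: str = "public_baseline"
    conv_filters: int = 64
    conv_kernel: int = 3
    pool_size: int = 2
    n_conv_blocks: int = 2
    gru_units: int = 8
    dense_units: int = 100
    lr: float = 0.01
    batch: int = 64
    iterations: int = 200

    def validate(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")

    @property
    def dropout(self) -> float:
        return {"bbs_model": 0.5, "public_baseline": 0.0,
                "public_complex": 0.7}[self.variant]

    @property
    def has_gru(self) -> bool:
        return self.variant in ("bbs_model", "public_complex")


class ReferenceClassifier(Module):
    """Conv/pool stack with a GRU or flatten head, per the variant spec."""

    def __init__(self, spec: ClassifierSpec, window_len: int, n_channels: int,
                 n_classes: int, *, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.n_channels = n_channels
        rng = np.random.default_rng(seed)
        self.convs = []
        in_ch, length = n_channels, window_len
        for _ in range(spec.n_conv_blocks):
            self.convs.append(Conv1D(in_ch, spec.conv_filters, spec.conv_kernel,
                                     rng, activation="relu"))
            in_ch = spec.conv_filters
            length //= spec.pool_size
        if length < 1:
            raise ValueError("window too short for the conv/pool stack")
        if spec.has_gru:
            self.gru = GRU(spec.conv_filters, spec.gru_units, rng)
            head_in = spec.gru_units
        else:
            self.gru = None
            head_in = length * spec.conv_filters
        self._flat_len = head_in
        self.drop = Dropout(spec.dropout, rng) if spec.dropout > 0 else None
        self.dense = Dense(head_in, spec.dense_units, rng, activation="relu")
        self.out = Dense(spec.dense_units, n_classes, rng)

    def logits(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        h = x
        for conv in self.convs:
            h = max_pool1d(conv(h), self.spec.pool_size)
        if self.gru is not None:
            h = self.gru(h)
        else:
            h = h.reshape(h.shape[0], self._flat_len)
        if self.drop is not None:
            h = self.drop(h)
        return self.out(self.dense(h))

    def forward(self, x) -> Tensor:
        return self.logits(x).softmax(axis=-1)

    __call__ = forward

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        self.eval()
        with no_grad():
            pred = self.forward(x).data.argmax(axis=1)
        return float((pred == np.asarray(y)).mean())


def build_classifier(spec: ClassifierSpec, window_len: int, n_channels: int,
                     n_classes: int, *, seed: int = 0) -> ReferenceClassifier:
    return ReferenceClassifier(spec, window_len, n_channels, n_classes, seed=seed)


def csd(values: ValueTable, record: CorruptionRecord,
        step_fraction: float = 0.05, n_steps: int = 10) -> CSDCurve:
    """Corrupted-sample discovery over the removal-fraction grid.

    ``v = round(step_fraction * N)`` samples are accumulated per step from
    the lowest value upward (stable sort, index tie-break); discovery at step
    r is |accumulated ∩ corrupted| / o.
    """
    if record.n_corrupted == 0:
        raise ValueError("no corruption record: o = 0")
    n = len(values)
    if n == 0:
        raise ValueError("empty value table")
    if not np.isin(record.indices, values.sample_index).all():
        raise ValueError("corruption record refers to samples outside the table")
    v = int(round(step_fraction * n))
    order = values.ascending_order()
    sorted_ids = values.sample_index[order]
    corrupted = set(record.indices.tolist())
    discovery = np.empty(n_steps + 1)
    optimal = np.empty(n_steps + 1)
    for r in range(n_steps + 1):
        taken = sorted_ids[:min(v * r, n)]
        hits = sum(1 for i in taken.tolist() if i in corrupted)
        discovery[r] = hits / record.n_corrupted
        optimal[r] = min(v * r / record.n_corrupted, 1.0)
    fractions = step_fraction * np.arange(n_steps + 1)
    return CSDCurve(fractions, discovery, optimal)


def _train_reference(spec: ClassifierSpec, x: np.ndarray, y: np.ndarray,
                     w: np.ndarray | None, n_classes: int, seed: int
                     ) -> ReferenceClassifier:
    model = ReferenceClassifier(spec, x.shape[1], x.shape[2], n_classes,
                                seed=seed)
    model.train()
    optimizer = Adam(model.parameters(), lr=spec.lr)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    batch = min(spec.batch, n)
    for _ in range(spec.iterations):
        idx = rng.choice(n, size=batch, replace=False)
        log_p = model.logits(x[idx]).log_softmax(axis=-1)
        ce = -log_p[np.arange(batch), y[idx]]
        if w is not None:
            ce = ce * Tensor(w[idx])
        loss = ce.mean()
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    return model


def rhlvs(ds: WindowedDataset, values: ValueTable,
          spec: ClassifierSpec | None = None, step_fraction: float = 0.05,
          n_steps: int = 10, *, seed: int = 0,
          weighted: bool = True) -> RHLVSCurve:
    """Remove high/low-value samples and retrain the reference classifier.

    For each r the classifier is retrained from scratch (one shared seed per
    curve, so r = 0 of both directions coincides) on the training split minus
    the v*r highest- (resp. lowest-) valued samples; remaining samples are
    weighted by their values unless ``weighted=False``.  Steps that would
    empty the training set truncate the curve with a warning.
    """
    spec = spec or ClassifierSpec()
    spec.validate()
    x_test, y_test = ds.subset("test")
    if x_test.shape[0] == 0:
        raise ValueError("test split is empty")
    n = len(values)
    v = int(round(step_fraction * n))
    order = values.ascending_order()          # lowest value first
    x_all = ds.signals[values.sample_index]
    y_all = ds.labels[values.sample_index]
    w_all = values.probs if weighted else None

    def run(keep_positions: np.ndarray) -> float:
        model = _train_reference(
            spec, x_all[keep_positions], y_all[keep_positions],
            None if w_all is None else w_all[keep_positions],
            ds.n_classes, seed)
        return model.accuracy(x_test, y_test)

    fractions, high_acc, low_acc = [], [], []
    for r in range(n_steps + 1):
        k = v * r
        if k >= n:
            warnings.warn(f"removal step {r} would empty the training set; "
                          "curve truncated", stacklevel=2)
            break
        low_removed = order[k:]       # drop the k lowest values
        high_removed = order[:n - k]  # drop the k highest values
        fractions.append(step_fraction * r)
        low_acc.append(run(low_removed))
        high_acc.append(run(high_removed))
    return RHLVSCurve(np.asarray(fractions), np.asarray(high_acc),
                      np.asarray(low_acc), spec.variant)
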