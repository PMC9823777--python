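"""Core containers shared by every stage of the valuation pipeline.

A :class:`WindowedDataset` is the universal currency: a stack of fixed-length
multichannel windows with integer class labels and a train/validation/test
split tag per window.  :class:`CorruptionRecord` remembers which training
labels were deliberately flipped (the ground truth for corrupted-sample
discovery) and :class:`ValueTable` holds the per-training-sample selection
probabilities the estimator produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SPLITS", "ChannelStats", "WindowedDataset", "CorruptionRecord",
           "ValueTable", "largest_remainder_allocation"]

SPLITS = ("train", "val", "test")


@dataclass
class ChannelStats:
    """Per-channel mean/sd computed on the training split, reused verbatim
    for validation and test."""

    mean: np.ndarray  # (C,)
    sd: np.ndarray    # (C,)


@dataclass
class WindowedDataset:
    signals: np.ndarray            # (N, W, C) float
    labels: np.ndarray             # (N,) int in 0..K-1
    split: np.ndarray              # (N,) str in SPLITS
    n_classes: int
    channel_stats: ChannelStats | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split, dtype="U5")
        if self.signals.ndim != 3:
            raise ValueError("signals must be (N, W, C)")
        n = self.signals.shape[0]
        if self.labels.shape != (n,) or self.split.shape != (n,):
            raise ValueError("labels/split must align with signals")
        if n and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels must lie in 0..n_classes-1")
        bad = set(np.unique(self.split)) - set(SPLITS)
        if bad:
            raise ValueError(f"unknown split tags: {sorted(bad)}")

    # -- basic views ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def window_len(self) -> int:
        return self.signals.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[2]

    def split_indices(self, split: str) -> np.ndarray:
        """Absolute dataset indices belonging to one split, in storage order."""
        if split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        return np.flatnonzero(self.split == split)

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.split_indices(split)
        return self.signals[idx], self.labels[idx]

    def copy(self) -> "WindowedDataset":
        return WindowedDataset(
            self.signals.copy(), self.labels.copy(), self.split.copy(),
            self.n_classes,
            None if self.channel_stats is None else ChannelStats(
                self.channel_stats.mean.copy(), self.channel_stats.sd.copy()),
        )

    def one_hot(self, idx: np.ndarray | None = None) -> np.ndarray:
        labels = self.labels if idx is None else self.labels[idx]
        out = np.zeros((labels.size, self.n_classes))
        out[np.arange(labels.size), labels] = 1.0
        return out


@dataclass
class CorruptionRecord:
    """Which training samples had their labels flipped, and from what.

    ``indices`` are absolute dataset indices (all within the training split);
    ``original_labels`` are the labels before flipping.
    """

    indices: np.ndarray
    original_labels: np.ndarray
    rate: float
    seed: int

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.original_labels = np.asarray(self.original_labels, dtype=np.int64)
        if self.indices.shape != self.original_labels.shape:
            raise ValueError("indices and original_labels must align")

    @property
    def n_corrupted(self) -> int:
        return self.indices.size


@dataclass
class ValueTable:
    """Selection probability (= data value) per training sample.

    ``sample_index`` maps each probability back to its absolute dataset index.
    """

    probs: np.ndarray         # (N_train,), each in (0, 1)
    sample_index: np.ndarray  # (N_train,) absolute indices into the dataset

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.sample_index = np.asarray(self.sample_index, dtype=np.int64)
        if self.probs.shape != self.sample_index.shape:
            raise ValueError("probs and sample_index must align")
        if self.probs.size and not ((self.probs > 0) & (self.probs < 1)).all():
            raise ValueError("values must lie strictly inside (0, 1)")

    def __len__(self) -> int:
        return self.probs.size

    def ascending_order(self) -> np.ndarray:
        """Positions sorted by value, lowest first; ties broken by index."""
        return np.lexsort((self.sample_index, self.probs))


def largest_remainder_allocation(n: int, fractions) -> np.ndarray:
    """Integer allocation of ``n`` items to fractions, summing exactly to n.

    Deterministic: remainders tie-break toward earlier entries.
    """
    fractions = np.asarray(fractions, dtype=np.float64)
    exact = n * fractions / fractions.sum()
    base = np.floor(exact).astype(np.int64)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base
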