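"""Windowing, normalization, zero-padding and oversampling for raw recordings.

Continuous multichannel recordings become fixed-length windows via a sliding
window with fractional overlap (the standard HAR configurations: window 128
with 50 % overlap for smartphone accelerometer/gyroscope data, 80 or 100 for
lower-rate sensors).  Normalization is a per-channel z-score whose statistics
come from the training split only and are reused verbatim for held-out
splits.  Oversampling augmentation balances class counts in the training
split by duplicating seeded-random samples with additive Gaussian jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ChannelStats, WindowedDataset

__all__ = ["WindowingConfig", "slide_windows", "normalize", "zero_pad",
           "oversample_augment", "decimate", "read_long_csv"]


@dataclass(frozen=True)
class WindowingConfig:
    window_len: int = 128
    overlap_fraction: float = 0.5
    pad_to: int | None = None

    @property
    def stride(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap_fraction)))

    def validate(self) -> None:
        if self.window_len < 1:
            raise ValueError("window_len must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.stride < 1:
            raise ValueError("stride rounds to zero; decrease overlap")
        if self.pad_to is not None and self.pad_to < self.window_len:
            raise ValueError("pad_to must be >= window_len")


def zero_pad(window: np.ndarray, target_len: int) -> np.ndarray:
    """Append zero timesteps up to ``target_len``; never truncates."""
    window = np.asarray(window, dtype=np.float64)
    length = window.shape[0]
    if length > target_len:
        raise ValueError(f"window length {length} exceeds target {target_len}")
    if length == target_len:
        return window.copy()
    pad = np.zeros((target_len - length,) + window.shape[1:])
    return np.concatenate([window, pad], axis=0)


def _window_label(labels: np.ndarray, start: int, window_len: int) -> int:
    """Majority label over the window's timesteps; ties -> label at midpoint."""
    seg = labels[start:start + window_len]
    values, counts = np.unique(seg, return_counts=True)
    winners = values[counts == counts.max()]
    if winners.size == 1:
        return int(winners[0])
    return int(labels[start + window_len // 2])


def slide_windows(series: np.ndarray, labels_per_timestep: np.ndarray,
                  cfg: WindowingConfig) -> list[tuple[np.ndarray, int]]:
    """Cut a (L, C) recording into overlapping (W, C) windows with labels.

    Windows start at 0, stride, 2*stride, ...; the count is
    ``floor((L - W) / stride) + 1``.  Recordings shorter than one window are
    zero-padded to ``cfg.pad_to`` when configured, otherwise rejected.
    """
    cfg.validate()
    series = np.asarray(series, dtype=np.float64)
    labels_per_timestep = np.asarray(labels_per_timestep)
    if series.ndim != 2:
        raise ValueError("series must be (L, C)")
    if labels_per_timestep.shape[0] != series.shape[0]:
        raise ValueError("labels_per_timestep must align with series")

    length, w = series.shape[0], cfg.window_len
    if length < w:
        if cfg.pad_to is None:
            raise ValueError(
                f"recording length {length} < window {w}; set pad_to to zero-pad")
        label = _window_label(labels_per_timestep, 0, length)
        return [(zero_pad(series, cfg.pad_to), label)]

    stride = cfg.stride
    n_windows = (length - w) // stride + 1
    out = []
    for i in range(n_windows):
        start = i * stride
        out.append((series[start:start + w].copy(),
                    _window_label(labels_per_timestep, start, w)))
    return out


def normalize(ds: WindowedDataset) -> WindowedDataset:
    """Per-channel z-score with statistics from the training split only.

    Zero-variance channels keep sd = 1 (with a warning) so constant channels
    map to zero instead of NaN.  Statistics are stored on the result and are
    exactly those applied to validation/test.
    """
    train_idx = ds.split_indices("train")
    if train_idx.size == 0:
        raise ValueError("training split is empty; cannot fit normalization")
    train = ds.signals[train_idx]
    mean = train.mean(axis=(0, 1))
    sd = train.std(axis=(0, 1))
    # accumulated float error makes a constant channel's sd ~1e-13, not 0
    zero_var = sd < 1e-10 * np.maximum(1.0, np.abs(mean))
    if zero_var.any():
        warnings.warn(
            f"channels {np.flatnonzero(zero_var).tolist()} have zero variance; "
            "sd replaced by 1", stacklevel=2)
        sd = np.where(zero_var, 1.0, sd)
    out = ds.copy()
    out.signals = (ds.signals - mean) / sd
    out.channel_stats = ChannelStats(mean=mean, sd=sd)
    return out


def oversample_augment(ds: WindowedDataset, target_per_class: int,
                       jitter_sd: float, seed: int) -> WindowedDataset:
    """Raise every training class to ``target_per_class`` windows.

    Minority classes are topped up by duplicating seeded-random training
    samples of that class with additive Gaussian jitter of sd
    ``jitter_sd * per-channel training sd``.  Classes already at or above the
    target are left untouched (with a warning when the target is below the
    current count).  Only the training split grows.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    train_idx = ds.split_indices("train")
    train_labels = ds.labels[train_idx]
    channel_sd = ds.signals[train_idx].std(axis=(0, 1))

    new_signals, new_labels = [], []
    for k in range(ds.n_classes):
        k_idx = train_idx[train_labels == k]
        if k_idx.size > target_per_class:
            warnings.warn(
                f"class {k} already has {k_idx.size} > target {target_per_class}; "
                "left unchanged", stacklevel=2)
            continue
        deficit = target_per_class - k_idx.size
        if deficit == 0 or k_idx.size == 0:
            continue
        picks = rng.choice(k_idx, size=deficit, replace=True)
        dup = ds.signals[picks].copy()
        if jitter_sd > 0:
            dup += rng.normal(0.0, jitter_sd * channel_sd, size=dup.shape)
        new_signals.append(dup)
        new_labels.append(np.full(deficit, k, dtype=np.int64))

    if not new_signals:
        return ds.copy()
    signals = np.concatenate([ds.signals] + new_signals, axis=0)
    labels = np.concatenate([ds.labels] + new_labels)
    split = np.concatenate([ds.split,
                            np.full(labels.size - ds.n_samples, "train")])
    return WindowedDataset(signals, labels, split, ds.n_classes,
                           channel_stats=ds.channel_stats)


def decimate(series: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by an integer factor by taking every ``factor``-th timestep.

    Plain decimation without an anti-aliasing filter; adequate for the
    oversampled clinical recordings it is meant for, documented as such.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.asarray(series)[::factor]


def read_long_csv(path, channel_columns: list[str],
                  label_column: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a long-format recording CSV: one row per timestep.

    Returns ``(series (L, C), labels_per_timestep (L,))``.
    """
    df = pd.read_csv(path)
    missing = [c for c in channel_columns + [label_column] if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing columns: {missing}")
    series = df[channel_columns].to_numpy(dtype=np.float64)
    labels = df[label_column].to_numpy()
    return series, labels
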