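"""Synthetic HAR-like multivariate time-series with known class structure.

Each class carries a deterministic periodic signature — a class-specific
fundamental frequency with per-channel amplitude and phase — on top of which
zero-mean Gaussian noise is added.  This mimics the gross structure of
wearable-IMU activity windows (quasi-periodic motion at activity-specific
cadence across accelerometer/gyroscope channels) while keeping ground truth
exact, so label corruption can be injected and later rediscovered by the
valuation algorithm.

The generator is the package's study-condition oracle: defaults follow the
evaluation protocol (4:2:3 train/validation/test split, 20 % label
corruption) and everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CorruptionRecord, WindowedDataset, largest_remainder_allocation

__all__ = ["SyntheticSpec", "generate", "corrupt_labels",
           "SPLIT_RATIO", "DEFAULT_CORRUPTION_RATE"]

# Train : validation : test ratio used throughout the evaluation protocol.
SPLIT_RATIO = (4, 2, 3)

# Fraction of training labels flipped when emulating contaminated data.
DEFAULT_CORRUPTION_RATE = 0.2

# --- class-signature constants (all in one place) -------------------------
# Class k oscillates at BASE + k * STEP cycles per window; channel c gets an
# amplitude from a small grid and a fixed phase offset.  Chosen so classes
# are linearly separable at low noise yet overlap enough at the default
# noise level that corrupted labels measurably hurt training.
_FREQ_BASE = 1.5          # cycles per window, class 0
_FREQ_STEP = 1.0          # extra cycles per window per class
_AMP_GRID = (1.0, 0.7, 0.5)   # cycled over (class + channel) % 3
_PHASE_PER_CHANNEL = 2.0 * np.pi / 7.0  # channel phase stagger (radians)
_CHANNEL_FREQ_SCALE = (1.0, 1.0, 1.0, 2.0, 2.0, 2.0)  # harmonics by channel


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 3
    n_per_class: int = 90
    window_len: int = 64
    n_channels: int = 6
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.window_len < 8:
            raise ValueError("window_len must be >= 8")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def class_signature(k: int, window_len: int, n_channels: int) -> np.ndarray:
    """Deterministic noise-free template for class ``k``, shape (W, C)."""
    t = np.arange(window_len) / window_len
    sig = np.empty((window_len, n_channels))
    freq = _FREQ_BASE + _FREQ_STEP * k
    for c in range(n_channels):
        amp = _AMP_GRID[(k + c) % len(_AMP_GRID)]
        harmonic = _CHANNEL_FREQ_SCALE[c % len(_CHANNEL_FREQ_SCALE)]
        phase = _PHASE_PER_CHANNEL * c
        sig[:, c] = amp * np.sin(2.0 * np.pi * freq * harmonic * t + phase)
    return sig


def generate(spec: SyntheticSpec) -> WindowedDataset:
    """Draw ``n_classes * n_per_class`` windows and assign 4:2:3 splits.

    Identical spec (including seed) yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.n_per_class
    signals = np.empty((n, spec.window_len, spec.n_channels))
    labels = np.repeat(np.arange(spec.n_classes), spec.n_per_class)
    for k in range(spec.n_classes):
        template = class_signature(k, spec.window_len, spec.n_channels)
        block = slice(k * spec.n_per_class, (k + 1) * spec.n_per_class)
        noise = rng.normal(0.0, spec.noise_sd,
                           size=(spec.n_per_class, spec.window_len, spec.n_channels)) \
            if spec.noise_sd > 0 else 0.0
        signals[block] = template[None, :, :] + noise

    counts = largest_remainder_allocation(n, SPLIT_RATIO)
    tags = np.concatenate([
        np.full(counts[0], "train"),
        np.full(counts[1], "val"),
        np.full(counts[2], "test"),
    ])
    split = tags[rng.permutation(n)]
    return WindowedDataset(signals, labels, split, n_classes=spec.n_classes)


def corrupt_labels(ds: WindowedDataset, rate: float,
                   seed: int) -> tuple[WindowedDataset, CorruptionRecord]:
    """Flip a fraction of training labels to a uniformly drawn *different* class.

    Exactly ``round(rate * N_train)`` training samples are chosen uniformly
    without replacement.  Validation/test labels are never touched.  Returns a
    corrupted copy and the record needed to score corrupted-sample discovery.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("corruption rate must be in [0, 1]")
    if ds.n_classes < 2:
        raise ValueError("need at least 2 classes to corrupt labels")
    train_idx = ds.split_indices("train")
    if train_idx.size == 0:
        raise ValueError("training split is empty")

    rng = np.random.default_rng(seed)
    n_flip = int(round(rate * train_idx.size))
    flip_idx = np.sort(rng.choice(train_idx, size=n_flip, replace=False))

    out = ds.copy()
    original = out.labels[flip_idx].copy()
    # uniform over the K-1 other classes: draw in 0..K-2 and shift past original
    draws = rng.integers(0, ds.n_classes - 1, size=n_flip)
    out.labels[flip_idx] = np.where(draws >= original, draws + 1, draws)
    record = CorruptionRecord(flip_idx, original, rate=rate, seed=seed)
    return out, record
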