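"""Shared fixtures.

The heavy end-to-end valuation runs (three seeds) are computed once per
session and shared by the separation and RHLVS-direction tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tsdval.data import WindowedDataset
from tsdval.evaluation import ClassifierSpec, rhlvs
from tsdval.preprocessing import normalize
from tsdval.synthetic import SyntheticSpec, corrupt_labels, generate
from tsdval.trainer import TrainerConfig, train_valuation

# Study conditions for the end-to-end checks: 3 classes, 270 windows,
# 20 % label corruption; compact inner/outer iteration counts sized for a
# single CPU (see docs/methods.md).
END_TO_END_SEEDS = (1, 2, 3)
SMALL_TRAINER = dict(N_I=50, outer_iters=15, pretrain_iters=100)
SMALL_CLASSIFIER = ClassifierSpec(iterations=60, batch=32)


def small_dataset(seed: int, corruption: float = 0.2):
    ds = normalize(generate(SyntheticSpec(seed=seed)))
    return corrupt_labels(ds, corruption, seed)


@pytest.fixture(scope="session")
def valuation_runs():
    """Full pipeline for three seeds: (dataset, record, table, rhlvs curve)."""
    runs = {}
    for seed in END_TO_END_SEEDS:
        ds, record = small_dataset(seed)
        table = train_valuation(ds, TrainerConfig(seed=seed, **SMALL_TRAINER))
        curve = rhlvs(ds, table, SMALL_CLASSIFIER, seed=seed)
        runs[seed] = (ds, record, table, curve)
    return runs


@pytest.fixture
def tiny_dataset():
    """A fast 2-class dataset for unit tests of training plumbing."""
    spec = SyntheticSpec(n_classes=2, n_per_class=18, window_len=16,
                        n_channels=2, noise_sd=0.2, seed=5)
    return normalize(generate(spec))


@pytest.fixture
def imbalanced_dataset():
    """Three classes with deliberately unequal training counts."""
    rng = np.random.default_rng(3)
    counts = {0: 12, 1: 5, 2: 8}
    signals, labels = [], []
    for k, c in counts.items():
        signals.append(rng.normal(size=(c, 16, 2)) + k)
        labels.extend([k] * c)
    signals = np.concatenate(signals)
    split = np.array(["train"] * len(labels))
    split[-3:] = "test"   # a few test samples so the container validates
    labels = np.array(labels)
    return WindowedDataset(signals, labels, split, n_classes=3)
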