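"""CSD and RHLVS statistics and the reference classifiers."""

from __future__ import annotations

import numpy as np
import pytest

from tsdval.data import CorruptionRecord, ValueTable
from tsdval.evaluation import (ClassifierSpec, build_classifier, csd, rhlvs)
from tsdval.preprocessing import normalize
from tsdval.synthetic import SyntheticSpec, corrupt_labels, generate


def make_table(values, indices=None):
    values = np.asarray(values, dtype=float)
    if indices is None:
        indices = np.arange(values.size)
    return ValueTable(values, np.asarray(indices))


def make_record(indices, rate=0.2):
    indices = np.asarray(indices)
    return CorruptionRecord(indices, np.zeros(indices.size, dtype=int),
                            rate=rate, seed=0)


def brute_force_csd(values, corrupted, step=0.05, n_steps=10):
    """Independent oracle: explicit sort + set intersection per step."""
    n = len(values)
    v = round(step * n)
    order = sorted(range(n), key=lambda i: (values[i], i))
    out = []
    for r in range(n_steps + 1):
        taken = set(order[:min(v * r, n)])
        out.append(len(taken & set(corrupted)) / len(corrupted))
    return np.array(out)


class TestCSD:
    def test_hand_enumerated_example(self):
        """20 samples, the 4 corrupted ones hold the 4 smallest values."""
        values = np.concatenate([[0.01, 0.02, 0.03, 0.04],
                                 np.linspace(0.5, 0.9, 16)])
        curve = csd(make_table(values), make_record([0, 1, 2, 3]))
        np.testing.assert_allclose(
            curve.discovery, [0, 0.25, 0.5, 0.75, 1, 1, 1, 1, 1, 1, 1])

    def test_agrees_with_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(10, 60))
            o = int(rng.integers(1, max(2, n // 3)))
            values = rng.random(n)
            corrupted = rng.choice(n, size=o, replace=False)
            curve = csd(make_table(values), make_record(corrupted, rate=o / n))
            expected = brute_force_csd(values, corrupted)
            np.testing.assert_array_equal(curve.discovery, expected)

    def test_random_values_mean_discovery_equals_removal_fraction(self):
        """E[CSD_r] = v*r/N under exchangeable values (10,000 shuffles)."""
        n, o, v = 40, 8, 2
        rng = np.random.default_rng(1)
        corrupted = np.arange(o)
        hits = np.zeros(11)
        base = np.arange(n)
        for _ in range(10_000):
            perm = rng.permutation(n)   # ranks are uniform: shuffle positions
            ranks = np.empty(n)
            ranks[perm] = base
            curve = csd(make_table(ranks / n + 1e-3),
                        make_record(corrupted, rate=o / n))
            hits += curve.discovery
        mean = hits / 10_000
        expected = np.minimum(v * np.arange(11) / n, 1.0)
        assert np.abs(mean - expected).max() < 0.01

    def test_invariance_under_monotone_transformation(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0.1, 0.9, 30)
        rec = make_record([3, 8, 15, 22, 29], rate=5 / 30)
        a = csd(make_table(values), rec)
        b = csd(make_table(values ** 3 / 2), rec)   # strictly monotone map
        np.testing.assert_array_equal(a.discovery, b.discovery)

    def test_structural_invariants_and_optimal_geometry(self):
        rng = np.random.default_rng(3)
        n = 120
        values = rng.random(n)
        corrupted = rng.choice(n, size=24, replace=False)  # 20 % of training
        curve = csd(make_table(values), make_record(corrupted, rate=0.2))
        assert curve.discovery[0] == 0
        assert (np.diff(curve.discovery) >= 0).all()
        assert (curve.discovery <= curve.optimal + 1e-12).all()
        # with 20 % corruption and 5 % steps the ideal curve saturates at r=4
        assert curve.optimal[3] < 1.0 and curve.optimal[4] == 1.0

    def test_empty_corruption_record_rejected(self):
        with pytest.raises(ValueError, match="o = 0"):
            csd(make_table(np.linspace(0.1, 0.9, 10)), make_record([]))


class TestClassifiers:
    @pytest.mark.parametrize("variant,dropout,has_gru", [
        ("bbs_model", 0.5, True),
        ("public_baseline", 0.0, False),
        ("public_complex", 0.7, True),
    ])
    def test_variant_structure(self, variant, dropout, has_gru):
        spec = ClassifierSpec(variant=variant)
        assert spec.dropout == dropout
        model = build_classifier(spec, 16, 2, 3, seed=0)
        assert (model.gru is not None) == has_gru
        model.eval()
        out = model.forward(np.random.default_rng(0).normal(size=(4, 16, 2))).data
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(variant="bogus").validate()


@pytest.fixture(scope="module")
def tiny_corrupted():
    ds = normalize(generate(SyntheticSpec(
        n_classes=2, n_per_class=30, window_len=16, n_channels=2,
        noise_sd=0.3, seed=4)))
    ds, rec = corrupt_labels(ds, 0.2, seed=4)
    return ds, rec


class TestRHLVS:
    def test_no_removal_accuracies_coincide(self, tiny_corrupted):
        ds, _ = tiny_corrupted
        tr = ds.split_indices("train")
        rng = np.random.default_rng(0)
        table = ValueTable(rng.uniform(0.2, 0.8, tr.size), tr)
        curve = rhlvs(ds, table, ClassifierSpec(iterations=4, batch=8),
                      n_steps=2, seed=0)
        assert curve.remove_high_acc[0] == curve.remove_low_acc[0]
        assert ((curve.remove_high_acc >= 0) & (curve.remove_high_acc <= 1)).all()

    def test_equal_values_remove_complementary_index_sets(self, tiny_corrupted):
        """With all values tied the stable index tie-break is deterministic."""
        ds, _ = tiny_corrupted
        tr = ds.split_indices("train")
        table = ValueTable(np.full(tr.size, 0.5), tr)
        a = rhlvs(ds, table, ClassifierSpec(iterations=2, batch=8),
                  n_steps=1, seed=1)
        b = rhlvs(ds, table, ClassifierSpec(iterations=2, batch=8),
                  n_steps=1, seed=1)
        np.testing.assert_array_equal(a.remove_high_acc, b.remove_high_acc)
        np.testing.assert_array_equal(a.remove_low_acc, b.remove_low_acc)

    def test_truncates_when_removal_would_empty_training(self, tiny_corrupted):
        ds, _ = tiny_corrupted
        tr = ds.split_indices("train")
        table = ValueTable(np.linspace(0.1, 0.9, tr.size), tr)
        with pytest.warns(UserWarning, match="truncated"):
            curve = rhlvs(ds, table, ClassifierSpec(iterations=1, batch=4),
                          step_fraction=0.5, n_steps=10, seed=0)
        assert len(curve.removal_fractions) < 11
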