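"""Windowing, normalization, padding and oversampling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsdval.preprocessing import (WindowingConfig, normalize,
                                  oversample_augment, decimate, slide_windows,
                                  zero_pad)
from tsdval.synthetic import SyntheticSpec, generate


class TestSlideWindows:
    @pytest.mark.parametrize("L,W,overlap,expected_starts", [
        (256, 128, 0.5, [0, 64, 128]),
        (128, 128, 0.5, [0]),              # exactly one window
        (200, 80, 0.5, [0, 40, 80, 120]),  # low-rate sensor configuration
    ])
    def test_window_starts_and_count(self, L, W, overlap, expected_starts):
        series = np.arange(L, dtype=float)[:, None]
        out = slide_windows(series, np.zeros(L, dtype=int),
                            WindowingConfig(W, overlap))
        assert len(out) == len(expected_starts)
        for (win, _), start in zip(out, expected_starts):
            assert win[0, 0] == start

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(L=st.integers(8, 400), W=st.integers(4, 64),
           overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]))
    def test_count_matches_closed_form(self, L, W, overlap):
        cfg = WindowingConfig(W, overlap)
        if L < W:
            return
        out = slide_windows(np.zeros((L, 2)), np.zeros(L, dtype=int), cfg)
        assert len(out) == (L - W) // cfg.stride + 1

    def test_majority_label_with_midpoint_tiebreak(self):
        labels = np.array([0] * 4 + [1] * 4)        # tie over an 8-long window
        out = slide_windows(np.zeros((8, 1)), labels, WindowingConfig(8, 0.0))
        assert out[0][1] == labels[4]                # label at the midpoint
        labels2 = np.array([0] * 5 + [1] * 3)
        out2 = slide_windows(np.zeros((8, 1)), labels2, WindowingConfig(8, 0.0))
        assert out2[0][1] == 0                       # clear majority

    def test_short_recording_needs_pad_to(self):
        with pytest.raises(ValueError):
            slide_windows(np.zeros((10, 1)), np.zeros(10, dtype=int),
                          WindowingConfig(16, 0.5))
        out = slide_windows(np.ones((10, 1)), np.zeros(10, dtype=int),
                            WindowingConfig(16, 0.5, pad_to=16))
        assert len(out) == 1 and out[0][0].shape == (16, 1)
        assert out[0][0][10:].sum() == 0


class TestZeroPad:
    def test_pads_with_zeros_and_preserves_content(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(50, 3))
        padded = zero_pad(w, 100)
        assert padded.shape == (100, 3)
        assert (padded[50:] == 0).all()
        assert padded.sum() == pytest.approx(w.sum())   # conservation

    def test_identity_and_truncation_error(self):
        w = np.ones((5, 2))
        np.testing.assert_array_equal(zero_pad(w, 5), w)
        with pytest.raises(ValueError):
            zero_pad(w, 4)


class TestNormalize:
    def test_training_split_becomes_zero_mean_unit_sd(self):
        ds = normalize(generate(SyntheticSpec(seed=1)))
        train = ds.signals[ds.split_indices("train")]
        np.testing.assert_allclose(train.mean(axis=(0, 1)), 0, atol=1e-6)
        np.testing.assert_allclose(train.std(axis=(0, 1)), 1, atol=1e-6)

    def test_heldout_uses_training_statistics(self):
        raw = generate(SyntheticSpec(seed=2))
        ds = normalize(raw)
        mu, sd = ds.channel_stats.mean, ds.channel_stats.sd
        test_idx = raw.split_indices("test")
        np.testing.assert_allclose(
            ds.signals[test_idx], (raw.signals[test_idx] - mu) / sd)

    def test_constant_channel_maps_to_zero_with_warning(self):
        raw = generate(SyntheticSpec(n_channels=2, seed=3))
        raw.signals[:, :, 1] = 4.2
        with pytest.warns(UserWarning, match="zero variance"):
            ds = normalize(raw)
        np.testing.assert_allclose(ds.signals[:, :, 1], 0, atol=1e-9)
        assert not np.isnan(ds.signals).any()

    def test_idempotent_on_training_split(self):
        once = normalize(generate(SyntheticSpec(seed=4)))
        twice = normalize(once)
        tr = once.split_indices("train")
        np.testing.assert_allclose(twice.signals[tr], once.signals[tr],
                                   atol=1e-6)


class TestOversampleAugment:
    def test_balances_training_classes(self, imbalanced_dataset):
        out = oversample_augment(imbalanced_dataset, 12, jitter_sd=0.05, seed=1)
        tr = out.split_indices("train")
        counts = np.bincount(out.labels[tr], minlength=3)
        assert (counts == counts.max()).all()
        # non-training samples untouched
        n_orig = imbalanced_dataset.n_samples
        assert (out.split[:n_orig] == imbalanced_dataset.split).all()
        assert (out.split[n_orig:] == "train").all()

    def test_zero_jitter_duplicates_exactly(self, imbalanced_dataset):
        out = oversample_augment(imbalanced_dataset, 12, jitter_sd=0.0, seed=1)
        extras = out.signals[imbalanced_dataset.n_samples:]
        originals = imbalanced_dataset.signals
        for e in extras:
            assert any((e == o).all() for o in originals)

    def test_target_below_count_warns_and_leaves_class(self, imbalanced_dataset):
        with pytest.warns(UserWarning, match="left unchanged"):
            out = oversample_augment(imbalanced_dataset, 8, jitter_sd=0.0, seed=1)
        tr = out.split_indices("train")
        counts = np.bincount(out.labels[tr], minlength=3)
        assert counts[0] == 12 and counts[1] == 8 and counts[2] == 8


def test_decimate_takes_every_kth_timestep():
    series = np.arange(20)[:, None]
    np.testing.assert_array_equal(decimate(series, 4).ravel(),
                                  [0, 4, 8, 12, 16])
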