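"""Selection sampling, baseline recursion, REINFORCE update, full training."""

from __future__ import annotations

import numpy as np
import pytest

from tsdval.dve import DataValueEstimator, selection_logprob
from tsdval.nn import Adam, Tensor, no_grad
from tsdval.predictor import DoubleHeadPredictor, PredictorConfig, \
    weighted_cross_entropy
from tsdval.trainer import (RewardState, TrainerConfig, inner_update,
                            reinforce_update, sample_selection,
                            train_valuation)


class TestSampleSelection:
    def test_seeded_reproducibility(self):
        p = np.random.default_rng(0).uniform(0.2, 0.8, 50)
        np.testing.assert_array_equal(sample_selection(p, 7),
                                      sample_selection(p, 7))

    def test_high_probability_limit(self):
        p = np.full(30, 1 - 1e-6)
        assert sample_selection(p, 0).sum() == 30

    def test_monte_carlo_frequency(self):
        p = np.full(20, 0.5)
        rng = np.random.default_rng(123)
        freq = np.mean([sample_selection(p, rng) for _ in range(10_000)], axis=0)
        assert (np.abs(freq - 0.5) < 0.02).all()

    def test_all_zero_guard_forces_max_probability_sample(self):
        p = np.array([1e-6, 1e-6, 2e-6])
        s = sample_selection(p, 0)
        assert s.sum() >= 1
        forced = sample_selection(np.full(3, 1e-12) + [0, 1e-12, 0], 0)
        assert forced.sum() == 1

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(ValueError):
            sample_selection(np.array([0.0, 0.5]), 0)


class TestBaseline:
    def test_recursion_matches_closed_form(self):
        """delta_k = L * (1 - ((T-1)/T)^k) for constant reward from delta_0 = 0."""
        state = RewardState()
        T, L = 20, 1.0
        for k in range(1, 101):
            state.update(L, T)
            expected = L * (1 - ((T - 1) / T) ** k)
            assert state.delta == pytest.approx(expected, abs=1e-10)

    def test_window_one_tracks_reward_exactly(self):
        state = RewardState(delta=0.7)
        state.update(0.123, T=1)
        assert state.delta == 0.123

    def test_first_update_example(self):
        state = RewardState()
        state.update(1.0, T=20)
        assert state.delta == pytest.approx(0.05, abs=1e-12)


class TestReinforceUpdate:
    def test_surrogate_gradient_matches_analytic_form(self):
        """d/dp of a*[s log p + (1-s) log(1-p)] on a 3-sample batch."""
        p0 = np.array([0.3, 0.6, 0.8])
        s = np.array([1.0, 0.0, 1.0])
        a = 0.7
        p = Tensor(p0, requires_grad=True)
        (a * selection_logprob(p, s)).backward()
        analytic = a * (s / p0 - (1 - s) / (1 - p0))
        np.testing.assert_allclose(p.grad, analytic, atol=1e-12)
        # central finite differences on the surrogate itself
        eps = 1e-6
        for i in range(3):
            pp, pm = p0.copy(), p0.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (a * selection_logprob(pp, s).item()
                   - a * selection_logprob(pm, s).item()) / (2 * eps)
            assert num == pytest.approx(analytic[i], abs=1e-4)

    def test_zero_advantage_leaves_estimator_unchanged(self):
        dve = DataValueEstimator(16, 2, 2, seed=0)
        opt = dve.make_optimizer(0.01)
        # one real step first so Adam state is nonzero
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 16, 2))
        y = np.eye(2)[rng.integers(0, 2, 4)]
        m = rng.uniform(0, 1, (4, 2))
        cfg = TrainerConfig()
        state = RewardState(delta=0.5)
        probs = dve.selection_probability(x, y, m)
        s = sample_selection(probs.data, 3)
        reinforce_update(opt, probs, s, 0.9, state, cfg)
        before = [p.data.copy() for p in dve.parameters()]
        probs = dve.selection_probability(x, y, m)
        s = sample_selection(probs.data, 4)
        reinforce_update(opt, probs, s, state.delta, state, cfg)  # advantage 0
        for b, p in zip(before, dve.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_baseline_updated_with_mean_reward(self):
        dve = DataValueEstimator(16, 2, 2, seed=0)
        opt = dve.make_optimizer(0.01)
        rng = np.random.default_rng(2)
        probs = dve.selection_probability(
            rng.normal(size=(3, 16, 2)), np.eye(2)[[0, 1, 0]],
            rng.uniform(0, 1, (3, 2)))
        draws = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        state = RewardState()
        reinforce_update(opt, probs, draws, np.array([0.4, 0.6]), state,
                         TrainerConfig(T=20))
        assert state.delta == pytest.approx(0.5 / 20, abs=1e-12)

    def test_non_finite_reward_aborts(self):
        dve = DataValueEstimator(16, 2, 2, seed=0)
        opt = dve.make_optimizer(0.01)
        probs = Tensor(np.array([0.5, 0.5]), requires_grad=True)
        with pytest.raises(FloatingPointError):
            reinforce_update(opt, probs, np.array([1.0, 0.0]), np.nan,
                             RewardState(), TrainerConfig())


class TestInnerUpdate:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 16, 2))
        y = rng.integers(0, 2, 8)
        model = DoubleHeadPredictor(16, 2, PredictorConfig(n_classes=2), seed=seed)
        return model, model.make_optimizer(), x, y

    def test_all_zero_selection_leaves_parameters_unchanged(self):
        model, opt, x, y = self._setup()
        before = [p.data.copy() for p in model.parameters()]
        inner_update(model, opt, x, y, np.zeros(8),
                     TrainerConfig(N_I=3, B_p=8), np.random.default_rng(0))
        for b, p in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_full_selection_single_step_equals_weighted_step(self):
        model_a, opt_a, x, y = self._setup(seed=5)
        model_b, opt_b, _, _ = self._setup(seed=5)
        cfg = TrainerConfig(N_I=1, B_p=8)
        inner_update(model_a, opt_a, x, y, np.ones(8), cfg,
                     np.random.default_rng(9))
        # the whole batch is drawn either way, so order cannot matter
        loss = weighted_cross_entropy(model_b, x, y, np.ones(8))
        opt_b.zero_grad()
        loss.backward()
        opt_b.step()
        for a, b in zip(model_a.parameters(), model_b.parameters()):
            np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_selected_subset_loss_decreases(self):
        losses = []
        for seed in (0, 1, 2):
            model, opt, x, y = self._setup(seed=seed)
            s = np.ones(8)
            start = weighted_cross_entropy(model, x, y, s).item()
            inner_update(model, opt, x, y, s, TrainerConfig(N_I=50, B_p=8),
                         np.random.default_rng(seed))
            losses.append(weighted_cross_entropy(model, x, y, s).item() - start)
        assert np.mean(losses) < 0


class TestTrainValuation:
    TINY = dict(N_I=2, B_p=8, outer_iters=2, n_draws=2, pretrain_iters=3)

    def test_zero_outer_iters_returns_untrained_uniform_values(self, tiny_dataset):
        cfg = TrainerConfig(seed=0, **{**self.TINY, "outer_iters": 0})
        table = train_valuation(tiny_dataset, cfg)
        tr = tiny_dataset.split_indices("train")
        assert len(table) == tr.size
        np.testing.assert_array_equal(table.sample_index, tr)
        np.testing.assert_allclose(table.probs, 0.5)   # zero-initialized head

    def test_shape_and_range_contract_invariant_to_outer_iters(self, tiny_dataset):
        short = train_valuation(tiny_dataset, TrainerConfig(seed=0, **self.TINY))
        cfg4 = TrainerConfig(seed=0, **{**self.TINY, "outer_iters": 4})
        long = train_valuation(tiny_dataset, cfg4)
        assert len(short) == len(long)
        for t in (short, long):
            assert ((t.probs > 0) & (t.probs < 1)).all()

    def test_reproducible_from_seed(self, tiny_dataset):
        cfg = TrainerConfig(seed=11, **self.TINY)
        a = train_valuation(tiny_dataset, cfg)
        b = train_valuation(tiny_dataset, cfg)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_degenerate_splits_rejected(self, tiny_dataset):
        broken = tiny_dataset.copy()
        broken.split[broken.split == "val"] = "test"
        with pytest.raises(ValueError):
            train_valuation(broken, TrainerConfig(**self.TINY))
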