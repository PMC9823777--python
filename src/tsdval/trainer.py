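"""REINFORCE training loop for the data value estimator.

One outer iteration:

1. draw a selection batch D_B of B_s training samples and query the value
   estimator for selection probabilities w_j = h(x_j, y_j);
2. draw ``n_draws`` independent binary selection vectors s ~ Bernoulli(w);
3. for each drawn selection, restore the predictor (and its optimizer state)
   to the warm-start snapshot and run N_I inner steps on B_p triples
   (x~, y~, s~) sampled from D_B, minimizing the selection-masked
   cross-entropy at learning rate alpha, then measure the mean cross-entropy
   L on the clean validation split;
4. update the estimator with the Monte-Carlo policy gradient
   mean_k [ (L_k - delta) * grad log pi(s_k) ], where log pi is the
   Bernoulli log-likelihood of the drawn selection and delta a
   moving-average baseline, plus a soft exploration penalty that keeps the
   mean selection probability inside a band;
5. update the baseline  delta <- ((T-1)/T) delta + mean_k L_k / T.

Selections whose validation loss lands below the baseline have their
probability pushed up, and vice versa.  Several stabilizers make the policy
gradient informative within few outer iterations on a single CPU (each is
discussed in the methods note):

* the predictor is warm-started once on the full training split and restored
  to that snapshot before every evaluation, so the reward is a function of
  the current selection alone rather than of selection history;
* the baseline starts at the warm-start validation loss instead of 0, so
  early advantages are centred;
* all draws within an outer iteration share the inner-loop minibatch
  sequence (common random numbers), so reward differences between draws
  reflect the selections and not the minibatch ordering;
* the reward cross-entropy floors predicted class probabilities, bounding
  the advantage a single diverged inner run can produce;
* an exploration penalty linear in the out-of-band excess of the mean
  selection probability blocks the two absorbing states (select-nothing and
  select-everything).

The returned :class:`~tsdval.data.ValueTable` holds h(x_i, y_i) for every
training sample, evaluated with dropout off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import ValueTable, WindowedDataset
from .dve import DataValueEstimator, DVEConfig, selection_logprob
from .nn import Adam, Tensor, no_grad
from .predictor import (DoubleHeadPredictor, PredictorConfig, fit_weighted,
                        marginal_information, pretrain_validation_predictor,
                        weighted_cross_entropy)

__all__ = ["TrainerConfig", "RewardState", "sample_selection", "inner_update",
           "reinforce_update", "train_valuation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainerConfig:
    alpha: float = 0.01       # predictor learning rate
    beta: float = 0.01        # value-estimator learning rate
    B_p: int = 64             # predictor mini-batch (64 small-data / 1024 large-data)
    B_s: int | None = None    # selection batch; None -> min(N_train, 4 * B_p)
    N_I: int = 200            # inner predictor steps per selection evaluation
    T: int = 20               # moving-average window of the baseline
    outer_iters: int = 30
    n_draws: int = 6          # Monte-Carlo selection draws per outer iteration
    pretrain_iters: int = 200  # warm-start steps for predictor and f_v
    seed: int = 0
    reward: str = "loss"      # "loss" (validation cross-entropy) or "accuracy"
    reward_prob_floor: float = 1e-3   # floor on predicted probs in the reward CE
    explore_band: tuple[float, float] = (0.1, 0.9)
    explore_weight: float = 1000.0

    def validate(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("learning rates must be positive")
        for name in ("B_p", "N_I", "T", "n_draws"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.outer_iters < 0 or self.pretrain_iters < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.B_s is not None and self.B_s < self.B_p:
            raise ValueError("B_s must be >= B_p")
        if self.reward not in ("loss", "accuracy"):
            raise ValueError("reward must be 'loss' or 'accuracy'")
        lo, hi = self.explore_band
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("explore_band must satisfy 0 <= lo < hi <= 1")

    def resolved_B_s(self, n_train: int) -> int:
        b_s = min(n_train, 4 * self.B_p) if self.B_s is None else min(self.B_s, n_train)
        return max(b_s, 1)


@dataclass
class RewardState:
    """Moving-average baseline delta of the validation loss."""

    delta: float = 0.0

    def update(self, reward: float, T: int) -> None:
        self.delta = (T - 1) / T * self.delta + reward / T


def sample_selection(probs: np.ndarray, seed: int | np.random.Generator,
                     max_resample: int = 10) -> np.ndarray:
    """Draw s_j ~ Bernoulli(p_j) independently, with an all-zero guard.

    An empty selection leaves the weighted loss undefined, so an all-zero
    draw is resampled up to ``max_resample`` times and, failing that, the
    highest-probability sample is force-selected.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if ((probs <= 0) | (probs >= 1)).any():
        raise ValueError("probabilities must lie strictly in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    for _ in range(max_resample + 1):
        s = (rng.random(probs.shape) < probs).astype(np.float64)
        if s.any():
            return s
    s = np.zeros_like(probs)
    s[probs.argmax()] = 1.0
    return s


def inner_update(model: DoubleHeadPredictor, optimizer: Adam,
                 x: np.ndarray, y: np.ndarray, s: np.ndarray,
                 cfg: TrainerConfig, rng: np.random.Generator) -> None:
    """N_I selection-masked gradient steps on the predictor.

    Each step draws B_p triples from the selection batch; the binary s~ masks
    each sample's cross-entropy, so unselected samples contribute zero
    gradient that step.
    """
    n = x.shape[0]
    b_p = min(cfg.B_p, n)
    for _ in range(cfg.N_I):
        idx = rng.choice(n, size=b_p, replace=False)
        loss = weighted_cross_entropy(model, x[idx], y[idx], s[idx])
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()


def reinforce_update(dve_optimizer: Adam, probs: Tensor, s: np.ndarray,
                     reward: float | np.ndarray, state: RewardState,
                     cfg: TrainerConfig) -> None:
    """One policy-gradient step on the value estimator, then baseline update.

    ``s`` may be a single selection vector (B,) with a scalar reward, or a
    stack (M, B) of draws with a length-M reward vector; the surrogate is the
    mean over draws of (reward_k - delta) * log pi(s_k), whose gradient is
    the REINFORCE estimator, plus the exploration penalty.  With reward =
    validation loss this raises the probability of selections that beat the
    baseline.  A zero advantage (inside the exploration band) leaves the
    estimator untouched; the baseline then absorbs the mean reward.
    """
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    rewards = np.atleast_1d(np.asarray(reward, dtype=np.float64))
    if rewards.shape[0] != s.shape[0]:
        raise ValueError("one reward per selection draw is required")
    if not np.isfinite(rewards).all():
        raise FloatingPointError(f"non-finite validation reward: {rewards}")

    advantages = rewards - state.delta
    if s.shape[0] > 1:
        # centring the advantages within the draw batch cancels the common
        # component of the gradient exactly (sum of advantages is zero), so
        # only the contrast between selections drives the update
        advantages = advantages - advantages.mean()
    surrogate = None
    for k in range(s.shape[0]):
        term = float(advantages[k]) * selection_logprob(probs, s[k])
        surrogate = term if surrogate is None else surrogate + term
    surrogate = surrogate * (1.0 / s.shape[0])

    lo, hi = cfg.explore_band
    mean_p = probs.mean()
    surrogate = surrogate + cfg.explore_weight * (
        (mean_p - hi).relu() + (lo - mean_p).relu())

    dve_optimizer.zero_grad()
    surrogate.backward()
    # skip the Adam step when the gradient vanishes identically (e.g. zero
    # advantage inside the band), so "no signal" never perturbs the estimator
    if any(p.grad is not None and p.grad.any() for p in dve_optimizer.params):
        dve_optimizer.step()
    state.update(float(rewards.mean()), cfg.T)


def _floored_cross_entropy(proba: np.ndarray, y: np.ndarray,
                           floor: float) -> float:
    proba = np.clip(proba, floor, None)
    proba = proba / proba.sum(axis=1, keepdims=True)
    return float(-np.log(proba[np.arange(y.size), y]).mean())


def _validation_reward(model: DoubleHeadPredictor, x_val: np.ndarray,
                       y_val: np.ndarray, cfg: TrainerConfig) -> float:
    if cfg.reward == "accuracy":
        # negated so that, like the loss, smaller is better
        return -model.accuracy(x_val, y_val)
    return _floored_cross_entropy(model.predict_proba(x_val),
                                  np.asarray(y_val, dtype=np.int64),
                                  cfg.reward_prob_floor)


def _snapshot(model: DoubleHeadPredictor, optimizer: Adam):
    return ([p.data.copy() for p in model.parameters()],
            [a.copy() for a in optimizer.m],
            [a.copy() for a in optimizer.v], optimizer.t)


def _restore(model: DoubleHeadPredictor, optimizer: Adam, snap) -> None:
    weights, m, v, t = snap
    for p, w in zip(model.parameters(), weights):
        p.data = w.copy()
    optimizer.m = [a.copy() for a in m]
    optimizer.v = [a.copy() for a in v]
    optimizer.t = t


def train_valuation(ds: WindowedDataset, cfg: TrainerConfig | None = None,
                    dve_cfg: DVEConfig | None = None,
                    pred_cfg: PredictorConfig | None = None,
                    *, return_models: bool = False):
    """Run the full valuation training and return the per-sample values.

    The training split may be label-corrupted; the validation split must be
    clean (it defines the reward).  Fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or TrainerConfig()
    cfg.validate()
    train_idx = ds.split_indices("train")
    if train_idx.size == 0 or ds.split_indices("val").size == 0:
        raise ValueError("both training and validation splits must be non-empty")

    x_train, y_train = ds.signals[train_idx], ds.labels[train_idx]
    x_val, y_val = ds.subset("val")
    onehot = ds.one_hot(train_idx)
    n_train = train_idx.size

    root = np.random.SeedSequence(cfg.seed)
    (s_fv, s_warm, s_dve, s_loop) = root.spawn(4)

    def seed_of(ss: np.random.SeedSequence) -> int:
        return int(ss.generate_state(1)[0] % (2 ** 31))

    pred_cfg = pred_cfg or PredictorConfig(n_classes=ds.n_classes,
                                           batch=cfg.B_p,
                                           lr=cfg.alpha,
                                           iterations=cfg.pretrain_iters)

    # frozen validation-pretrained predictor -> marginal information, computed once
    f_v = pretrain_validation_predictor(ds, pred_cfg, seed=seed_of(s_fv))
    marginal = marginal_information(f_v, x_train, y_train, ds.n_classes)

    # predictor warm start on the full training split; snapshot for restores
    predictor = fit_weighted(ds, None, pred_cfg, seed=seed_of(s_warm))
    pred_optimizer = predictor.make_optimizer()
    pred_optimizer.lr = cfg.alpha
    warm = _snapshot(predictor, pred_optimizer)

    dve = DataValueEstimator(ds.window_len, ds.n_channels, ds.n_classes,
                             dve_cfg, seed=seed_of(s_dve))
    dve_optimizer = dve.make_optimizer(cfg.beta)
    state = RewardState(delta=_validation_reward(predictor, x_val, y_val, cfg))
    rng = np.random.default_rng(seed_of(s_loop))
    b_s = cfg.resolved_B_s(n_train)

    for it in range(cfg.outer_iters):
        batch = rng.choice(n_train, size=b_s, replace=False)
        dve.train()
        probs = dve.selection_probability(x_train[batch], onehot[batch],
                                          marginal[batch])
        # common random numbers: every draw sees the same minibatch sequence
        inner_seed = int(rng.integers(2 ** 31))
        draws = np.empty((cfg.n_draws, b_s))
        rewards = np.empty(cfg.n_draws)
        for k in range(cfg.n_draws):
            _restore(predictor, pred_optimizer, warm)
            draws[k] = sample_selection(probs.data, rng)
            inner_update(predictor, pred_optimizer,
                         x_train[batch], y_train[batch], draws[k], cfg,
                         np.random.default_rng(inner_seed))
            rewards[k] = _validation_reward(predictor, x_val, y_val, cfg)
        reinforce_update(dve_optimizer, probs, draws, rewards, state, cfg)
        logger.info("outer %d/%d: reward=%.4f baseline=%.4f mean_value=%.4f",
                    it + 1, cfg.outer_iters, float(rewards.mean()),
                    state.delta, float(probs.data.mean()))

    dve.eval()
    with no_grad():
        values = dve.selection_probability(x_train, onehot, marginal).data
    table = ValueTable(values, train_idx)
    if return_models:
        return table, dve, predictor, f_v
    return table
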