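"""Training: stratified splitting, the cross-entropy objective, AdamW loop.

The default objective is the summed binary cross-entropy over all species
outputs of the softmax posterior,

    loss = - sum_n [ y_n log(p_n) + (1 - y_n) log(1 - p_n) ],

averaged over the batch; the canonical multiclass form -log p_true is
available as ``loss="softmax_ce"``.  Optimisation uses decoupled-weight-
decay Adam (AdamW) with a step-wise learning-rate decay (factor 0.1 every
10 epochs by default).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import BirdcallNet, ModelConfig

EPS = 1e-12


@dataclasses.dataclass
class TrainConfig:
    """Optimisation schedule; defaults are the full-scale settings
    (70 epochs, batch 256, lr 1e-4, decay 0.1 per 10 epochs, AdamW).
    Desk-scale runs override epochs/batch/lr and may pool timesteps."""

    epochs: int = 70
    batch_size: int = 256
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    weight_decay: float = 0.01
    loss: str = "paper_bce"     # or "softmax_ce"
    grad_clip: float = 1.0      # global gradient-norm ceiling (0: off)
    seed: int = 0
    time_pool: int = 1          # average-pool the time axis by this factor
    eval_every: int = 0         # 0: skip per-epoch test metrics

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclasses.dataclass
class SplitResult:
    train_records: pd.DataFrame
    test_records: pd.DataFrame


def stratified_split(records: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int = 0) -> SplitResult:
    """Per-class seeded shuffle, then split at floor(0.8 * n_class) (4:1)."""
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for _, grp in records.groupby("species_id", sort=True):
        if len(grp) < 2:
            raise ValueError(
                f"class {grp['species_id'].iloc[0]!r} has < 2 records")
        idx = rng.permutation(len(grp))
        n_train = int(np.floor((1.0 - test_fraction) * len(grp)))
        train_parts.append(grp.iloc[idx[:n_train]])
        test_parts.append(grp.iloc[idx[n_train:]])
    return SplitResult(
        train_records=pd.concat(train_parts).reset_index(drop=True),
        test_records=pd.concat(test_parts).reset_index(drop=True),
    )


def cross_entropy_loss(pred: np.ndarray, target: np.ndarray,
                       form: str = "paper_bce") -> float:
    """Loss between predicted probabilities and one-hot targets (batched
    rows allowed; batch losses are averaged). Predictions are clamped to
    [1e-12, 1 - 1e-12] before the logarithms."""
    p = np.clip(np.atleast_2d(np.asarray(pred, dtype=float)), EPS, 1 - EPS)
    y = np.atleast_2d(np.asarray(target, dtype=float))
    if form == "paper_bce":
        per = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=1)
    elif form == "softmax_ce":
        per = -(y * np.log(p)).sum(axis=1)
    else:
        raise ValueError(f"unknown loss form {form!r}")
    return float(per.mean())


def _loss_tensor(probs: Tensor, onehot: np.ndarray, form: str) -> Tensor:
    p = probs.clip(EPS, 1 - EPS)
    y = Tensor(onehot)
    if form == "paper_bce":
        per = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).sum(axis=1)
    elif form == "softmax_ce":
        per = -(y * p.log()).sum(axis=1)
    else:
        raise ValueError(f"unknown loss form {form!r}")
    return per.mean()


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float,
                 weight_decay: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``;
    returns the pre-clip norm.  Standard stabiliser for recurrent nets."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


def pool_time(X: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool the last (time) axis by ``factor`` (desk-scale shrink)."""
    if factor <= 1:
        return X
    T = X.shape[-1] // factor * factor
    Xt = X[..., :T]
    return Xt.reshape(*Xt.shape[:-1], T // factor, factor).mean(axis=-1)


def epoch_lr(config: TrainConfig, epoch: int) -> float:
    """Learning rate in 1-based ``epoch`` under the step decay schedule."""
    n_decays = (epoch - 1) // config.lr_decay_every
    return config.learning_rate * config.lr_decay_factor**n_decays


@dataclasses.dataclass
class TrainResult:
    model: BirdcallNet
    log: pd.DataFrame  # epoch, lr, train_loss [, test_acc, test_map]


def train(X: np.ndarray, y: np.ndarray, model_config: ModelConfig,
          config: TrainConfig,
          X_test: np.ndarray | None = None,
          y_test: np.ndarray | None = None) -> TrainResult:
    """Mini-batch AdamW optimisation of a :class:`BirdcallNet`.

    ``X``: (N, n_features, T) feature maps; ``y``: integer labels.
    Deterministic for a fixed config seed (single-threaded execution).
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    X = pool_time(np.asarray(X), config.time_pool)
    if X_test is not None:
        X_test = pool_time(np.asarray(X_test), config.time_pool)
    n_species = model_config.n_species
    onehot = np.eye(n_species)[y]
    model = BirdcallNet(model_config)
    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    rows = []
    for epoch in range(1, config.epochs + 1):
        opt.lr = epoch_lr(config, epoch)
        order = rng.permutation(len(X))
        losses = []
        for lo in range(0, len(X), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            probs = model.forward(Tensor(X[idx]), train=True, rng=rng)
            loss = _loss_tensor(probs, onehot[idx], config.loss)
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                clip_grad_norm(opt.params, config.grad_clip)
            opt.step()
            losses.append(loss.data.item())
        row = {"epoch": epoch, "lr": opt.lr,
               "train_loss": float(np.mean(losses))}
        if (config.eval_every and X_test is not None
                and epoch % config.eval_every == 0):
            from .evaluation import evaluate_scores
            scores = model.predict_proba(X_test)
            rep = evaluate_scores(scores, np.asarray(y_test))
            row["test_acc"] = rep.accuracy
            row["test_map"] = rep.map_score
        rows.append(row)
    return TrainResult(model=model, log=pd.DataFrame(rows))
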