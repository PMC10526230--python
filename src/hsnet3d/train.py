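"""Training loop: multi-task loss, SGD/Adam/RMSProp with an optional
triangular cyclical learning rate, stochastic weight averaging, and
early-stopping checkpoint selection on validation main-head accuracy.

The multi-task loss is a weighted sum of per-head binary cross-entropies
over the five semantic tasks and the malignancy task.  With SWA enabled,
end-of-epoch weight snapshots from ``swa_start_epoch`` onward are folded
into a running average, W_swa <- (W_swa * n + W) / (n + 1), and the
batch-normalization statistics of the averaged model are recomputed over
the training set before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn.network import MultiTaskNet3D
from ._nn.optim import make_optimizer, clr_schedule, swa_update  # noqa: F401  (re-exported API)
from .models import ArchConfig, build_model
from .semantics import ALL_FEATURES

__all__ = ["TrainConfig", "TrainHistory", "TrainingDiverged", "multitask_loss",
           "clr_schedule", "swa_update", "train", "run_comparison_grid"]

_EPS = 1e-7


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "sgd"
    momentum: float = 0.9
    base_lr: float = 2e-3
    max_lr: float = 8e-3
    clr_step_epochs: float = 2.0     # half-cycle length, in epochs of iterations
    use_clr: bool = True
    use_swa: bool = True
    swa_start_epoch: int | None = None   # None = 0.75 * epochs
    epochs: int = 300
    batch_size: int = 16
    loss_weights: tuple = (1.0,) * 6
    early_stop: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.base_lr > self.max_lr:
            raise ValueError("base_lr must not exceed max_lr")
        if len(self.loss_weights) != 6:
            raise ValueError("loss_weights must have exactly 6 entries")
        if any(w < 0 or not np.isfinite(w) for w in self.loss_weights):
            raise ValueError("loss_weights must be finite and non-negative")
        if self.swa_start_epoch is not None and self.swa_start_epoch > self.epochs:
            raise ValueError("swa_start_epoch must not exceed epochs")

    def resolved_swa_start(self) -> int:
        if self.swa_start_epoch is not None:
            return self.swa_start_epoch
        return int(0.75 * self.epochs)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)        # per-epoch metric dicts
    learning_rates: list = field(default_factory=list)  # per-iteration lr
    checkpoint_epoch: int | None = None               # argmax val main accuracy

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame(self.epochs)


def multitask_loss(probs: np.ndarray, labels: np.ndarray, weights=None):
    """Weighted sum of per-head binary cross-entropies, averaged over samples.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient with
    respect to the pre-sigmoid logits, ready for backpropagation.
    Probabilities are clipped to (eps, 1-eps) before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape or probs.ndim != 2 or probs.shape[1] != 6:
        raise ValueError("probs and labels must both be (n, 6)")
    w = np.ones(6) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (6,):
        raise ValueError("need exactly 6 loss weights")
    n = probs.shape[0]
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    bce = -(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p))
    loss = float((bce.mean(axis=0) * w).sum())
    dlogits = (p - labels) * w / n
    return loss, dlogits.astype(np.float32)


def _accuracies(probs: np.ndarray, labels: np.ndarray) -> dict:
    pred = probs >= 0.5
    return {feat: float((pred[:, j] == (labels[:, j] > 0.5)).mean())
            for j, feat in enumerate(ALL_FEATURES)}


def _evaluate(model, x, y, weights, batch_size=64):
    probs = model.predict_proba(x, batch_size=batch_size)
    loss, _ = multitask_loss(probs, y, weights)
    return loss, _accuracies(probs, y)


def train(model: MultiTaskNet3D, train_set, val_set, cfg: TrainConfig):
    """Train in place; returns ``(model, history)`` with the returned model
    carrying the selected weights.

    ``train_set`` and ``val_set`` are ``(X, y)`` pairs with X of shape
    (n, D, D, D) and y binary (n, 6) in canonical head order.  Weight
    selection: with SWA the returned weights are the stochastic weight
    average (with refreshed BN statistics); otherwise, with early
    stopping, the end-of-epoch checkpoint with the highest validation
    malignancy (main-head) accuracy; otherwise the final weights.
    """
    x_train, y_train = train_set
    x_val, y_val = val_set
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    model.rng = np.random.default_rng(rng.integers(2 ** 31))  # dropout stream
    params = model.parameters()
    opt = make_optimizer(cfg.optimizer, params, momentum=cfg.momentum)
    weights = np.asarray(cfg.loss_weights, dtype=float)

    n = x_train.shape[0]
    iters_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    step_size = max(1, int(round(cfg.clr_step_epochs * iters_per_epoch)))
    swa_start = cfg.resolved_swa_start()

    history = TrainHistory()
    w_swa, n_models = None, 0
    best_val, best_snap, best_epoch = -np.inf, None, None
    iteration = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_correct, ep_count = 0.0, np.zeros(6), 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            lr = (clr_schedule(iteration, cfg.base_lr, cfg.max_lr, step_size)
                  if cfg.use_clr else cfg.base_lr)
            history.learning_rates.append(lr)
            probs = model.forward(xb, train=True)
            loss, dlogits = multitask_loss(probs, yb, weights)
            if not np.isfinite(loss):
                raise TrainingDiverged(epoch)
            model.backward(dlogits)
            opt.step(model.gradients(), lr)
            iteration += 1
            ep_loss += loss * len(idx)
            ep_correct += ((probs >= 0.5) == (yb > 0.5)).sum(axis=0)
            ep_count += len(idx)

        val_loss, val_acc = _evaluate(model, x_val, y_val, weights)
        record = {
            "epoch": epoch,
            "train_loss": ep_loss / ep_count,
            "val_loss": val_loss,
        }
        record.update({f"train_acc_{f}": ep_correct[j] / ep_count
                       for j, f in enumerate(ALL_FEATURES)})
        record.update({f"val_acc_{f}": v for f, v in val_acc.items()})
        history.epochs.append(record)

        if cfg.early_stop and val_acc["malignancy"] > best_val:
            best_val = val_acc["malignancy"]
            best_snap = model.snapshot()
            best_epoch = epoch
        if cfg.use_swa and epoch >= swa_start:
            w_swa = swa_update(w_swa, n_models, params)
            n_models += 1

    history.checkpoint_epoch = best_epoch
    if cfg.use_swa and n_models > 0:
        for k, v in w_swa.items():
            params[k][...] = v
        model.refresh_bn_stats(x_train, batch_size=cfg.batch_size)
    elif cfg.early_stop and best_snap is not None:
        model.load_snapshot(best_snap)
    return model, history


#: The five optimization-strategy runs compared in the training study.
COMPARISON_RUNS = {
    "Run1": dict(optimizer="sgd", use_clr=False, use_swa=False),
    "Run2": dict(optimizer="adam", use_clr=False, use_swa=False),
    "Run3": dict(optimizer="sgd", use_clr=True, use_swa=False),
    "Run4": dict(optimizer="sgd", use_clr=True, use_swa=True),
    "Run5": dict(optimizer="rmsprop", use_clr=True, use_swa=True),
}


def run_comparison_grid(train_set, val_set, test_set, arch: ArchConfig,
                        base_cfg: TrainConfig, runs: dict | None = None):
    """Train one model per optimization strategy on identical data and seed.

    Returns a dict run-name -> {config overrides, test accuracy per head}.
    """
    runs = COMPARISON_RUNS if runs is None else runs
    x_test, y_test = test_set
    results = {}
    for name, overrides in runs.items():
        cfg = TrainConfig(**{**base_cfg.as_dict(), **overrides})
        model = build_model(arch, seed=cfg.seed)
        model, history = train(model, train_set, val_set, cfg)
        probs = model.predict_proba(x_test)
        results[name] = {
            "overrides": dict(overrides),
            "test_accuracy": _accuracies(probs, y_test),
        }
    return results
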