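"""Seeded training loop: Adam, step learning-rate decay, early stopping.

The protocol: Adam (lr 1e-3, betas 0.9/0.999, L2 weight decay 1e-4), the
learning rate halved every 50 epochs, at most 300 epochs with batch size 64,
early stopping on validation loss with patience 30, 10% of the training data
held out (stratified) for validation, and the best-validation weights
restored at the end.  All randomness (validation split, batch shuffling,
dropout) is driven by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from ._nn import Adam, softmax_cross_entropy

__all__ = ["TrainConfig", "train_network"]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    lr_step: int = 50
    lr_factor: float = 0.5
    max_epochs: int = 300
    batch: int = 64
    patience: int = 30
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if min(self.lr, self.lr_step, self.lr_factor, self.max_epochs, self.batch, self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in effect during `epoch` (0-based)."""
        return self.lr * self.lr_factor ** (epoch // self.lr_step)


def _batch_loss(net, X, y, batch: int) -> float:
    total = 0.0
    for s in range(0, len(X), batch):
        logits = net.forward(X[s : s + batch], train=False)
        loss, _, _ = softmax_cross_entropy(logits, y[s : s + batch])
        total += loss * len(logits)
    return total / len(X)


def train_network(net, X, y, cfg: TrainConfig, val=None) -> dict:
    """Train `net` in place on ``(X (n,Nb,C,T), y (n,))``; returns the history.

    `val` is an optional explicit ``(X_val, y_val)`` pair; by default a
    stratified `val_fraction` of the data is held out for early stopping.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) != len(y) or len(X) == 0:
        raise ValueError("X and y must be non-empty and aligned")

    if val is None:
        idx_tr, idx_va = train_test_split(
            np.arange(len(X)),
            test_size=cfg.val_fraction,
            stratify=y,
            random_state=cfg.seed,
        )
        X_tr, y_tr, X_va, y_va = X[idx_tr], y[idx_tr], X[idx_va], y[idx_va]
    else:
        X_tr, y_tr = X, y
        X_va, y_va = val
        X_va = np.asarray(X_va, dtype=np.float64)
        y_va = np.asarray(y_va, dtype=np.int64)
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("training and validation sets must be non-empty")

    opt = Adam(
        net.params(),
        lr=cfg.lr,
        beta1=cfg.beta1,
        beta2=cfg.beta2,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": [], "lr": [], "best_epoch": None}
    best_loss, best_state, since_best = np.inf, net.get_state(), 0

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(len(X_tr))
        ep_loss = 0.0
        for s in range(0, len(order), cfg.batch):
            sel = order[s : s + cfg.batch]
            opt.zero_grad()
            logits = net.forward(X_tr[sel], train=True)
            loss, _, dlogits = softmax_cross_entropy(logits, y_tr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch} (loss={loss})")
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
        val_loss = _batch_loss(net, X_va, y_va, cfg.batch)
        history["train_loss"].append(ep_loss / len(X_tr))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)

        if val_loss < best_loss - 1e-12:
            best_loss, best_state, since_best = val_loss, net.get_state(), 0
            history["best_epoch"] = epoch
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    net.set_state(best_state)
    return history
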