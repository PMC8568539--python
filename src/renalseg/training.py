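"""Dice-loss training: loss, step schedule, Adam loop, best-loss checkpoint.

The loss for predicted foreground probabilities h and one-hot targets k is

    1 - (2*sum(h*k) + eps) / (sum(h^2) + sum(k^2) + eps)

evaluated over all pixels of a batch on the kidney class only (the
background class is implied by the softmax); a config switch averages over
both classes instead. The learning rate is 1e-3 for the first 30 epochs
and 1e-4 afterwards; "momentum 0.95" is applied as Adam's beta1, and the
1e-4 weight decay as classical L2 coupled into the Adam update.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np

from .nn.optim import Adam

__all__ = ["TrainConfig", "TrainLog", "dice_loss", "dice_loss_grad",
           "lr_schedule", "train"]


@dataclass
class TrainConfig:
    batch_size: int = 16
    lr_initial: float = 1e-3
    lr_after_epoch30: float = 1e-4
    lr_switch_epoch: int = 30  # last epoch that still uses lr_initial
    adam_beta1: float = 0.95
    adam_beta2: float = 0.999
    weight_decay: float = 1e-4
    max_epochs: int = 50
    max_steps: int | None = None
    seed: int = 0
    smoothing_eps: float = 1e-6
    loss_classes: str = "foreground"  # "foreground" | "both"
    val_fraction: float = 0.0

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if min(self.lr_initial, self.lr_after_epoch30) <= 0:
            raise ValueError("learning rates must be positive")
        if self.smoothing_eps < 0:
            raise ValueError("smoothing_eps must be non-negative")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.loss_classes not in ("foreground", "both"):
            raise ValueError("loss_classes must be 'foreground' or 'both'")


@dataclass
class TrainLog:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_lr: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 1-based

    @property
    def selection_loss(self) -> list[float]:
        return self.val_loss if self.val_loss else self.epoch_loss

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            cols = "epoch,loss,lr,seconds" + (",val_loss" if self.val_loss else "")
            fh.write(cols + "\n")
            for i, (loss, lr, sec) in enumerate(
                    zip(self.epoch_loss, self.epoch_lr, self.epoch_seconds)):
                row = f"{i + 1},{loss:.8f},{lr:g},{sec:.3f}"
                if self.val_loss:
                    row += f",{self.val_loss[i]:.8f}"
                fh.write(row + "\n")


def _per_class_dice_terms(h: np.ndarray, k: np.ndarray, eps: float):
    inter = float((h * k).sum())
    denom = float((h * h).sum() + (k * k).sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps), inter, denom


def dice_loss(probs: np.ndarray, target: np.ndarray, eps: float = 1e-6,
              loss_classes: str = "foreground") -> float:
    """Soft Dice loss over a batch.

    ``probs``: (N, 2, H, W) class probabilities (or a bare foreground map of
    any shape). ``target``: integer/binary mask broadcastable to the
    foreground map. Returns a scalar in [0, 1].
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    if probs.ndim == target.ndim + 1:  # (N,C,...) vs (N,...)
        classes = [1] if loss_classes == "foreground" else list(range(probs.shape[1]))
        losses = []
        for c in classes:
            h = probs[:, c]
            k = (target == c).astype(np.float64)
            losses.append(_per_class_dice_terms(h, k, eps)[0])
        return float(np.mean(losses))
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    return _per_class_dice_terms(probs, target.astype(np.float64), eps)[0]


def dice_loss_grad(probs: np.ndarray, target: np.ndarray, eps: float = 1e-6,
                   loss_classes: str = "foreground"):
    """Loss value and gradient w.r.t. the full probability tensor (N,C,H,W)."""
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    grad = np.zeros_like(probs)
    classes = [1] if loss_classes == "foreground" else list(range(probs.shape[1]))
    losses = []
    for c in classes:
        h = probs[:, c]
        k = (target == c).astype(np.float64)
        loss, inter, denom = _per_class_dice_terms(h, k, eps)
        losses.append(loss)
        d = denom + eps
        # d/dh of 1 - (2*inter+eps)/d
        grad[:, c] = (-2.0 * k * d + (2.0 * inter + eps) * 2.0 * h) / (d * d)
    grad /= len(classes)
    return float(np.mean(losses)), grad


def lr_schedule(epoch: int, cfg: TrainConfig = TrainConfig()) -> float:
    """Learning rate for a 1-based epoch index."""
    if epoch < 1 or epoch > cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [1, {cfg.max_epochs}]")
    return cfg.lr_initial if epoch <= cfg.lr_switch_epoch else cfg.lr_after_epoch30


def _stack(samples, dtype):
    images = np.stack([np.asarray(s.image) for s in samples]).astype(dtype)
    masks = np.stack([np.asarray(s.mask).astype(np.int64) for s in samples])
    return images[:, None], masks


def train(model, samples, cfg: TrainConfig = TrainConfig(), verbose: bool = False):
    """Train with Adam + Dice loss; return (best_state_dict, TrainLog).

    The returned weights are those of the epoch with the smallest mean
    training loss (or validation loss when ``val_fraction`` > 0).
    """
    if len(samples) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    dtype = model.classifier.weight.data.dtype

    samples = list(samples)
    n_val = int(round(cfg.val_fraction * len(samples)))
    if n_val:
        order = rng.permutation(len(samples))
        val_samples = [samples[i] for i in order[:n_val]]
        samples = [samples[i] for i in order[n_val:]]
        if not samples:
            raise ValueError("val_fraction leaves no training samples")
    else:
        val_samples = []

    opt = Adam(model.parameters(), lr=cfg.lr_initial, beta1=cfg.adam_beta1,
               beta2=cfg.adam_beta2, weight_decay=cfg.weight_decay)
    log = TrainLog()
    best_loss = np.inf
    best_state = model.state_dict()
    steps = 0
    n = len(samples)
    model.train()
    for epoch in range(1, cfg.max_epochs + 1):
        t0 = time.time()
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [samples[i] for i in order[start:start + cfg.batch_size]]
            x, y = _stack(batch, dtype)
            probs = model.forward(x)
            loss, gprobs = dice_loss_grad(probs, y, cfg.smoothing_eps,
                                          cfg.loss_classes)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss!r} at epoch {epoch}, step {steps}")
            model.zero_grad()
            model.backward(gprobs.astype(dtype))
            opt.step()
            epoch_losses.append(loss)
            steps += 1
            if verbose:
                print(f"  epoch {epoch} step {steps}: loss {loss:.4f}")
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
        mean_loss = float(np.mean(epoch_losses))
        log.epoch_loss.append(mean_loss)
        log.epoch_lr.append(lr)
        log.epoch_seconds.append(time.time() - t0)
        if val_samples:
            vx, vy = _stack(val_samples, dtype)
            model.eval()
            vprobs = model.predict_probs(np.squeeze(vx, axis=1))
            vloss = dice_loss(vprobs, vy, cfg.smoothing_eps, cfg.loss_classes)
            model.train()
            log.val_loss.append(float(vloss))
        select = log.selection_loss[-1]
        if select < best_loss:
            best_loss = select
            best_state = copy.deepcopy(model.state_dict())
            log.best_epoch = epoch
        if cfg.max_steps is not None and steps >= cfg.max_steps:
            break
    model.eval()
    return best_state, log
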