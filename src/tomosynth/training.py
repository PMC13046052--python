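"""Losses and the training loop.

The composite objective is generalized Dice + categorical cross-entropy.
The generalized Dice term weights each class by the squared inverse of its
volume in the target, so the scarce bone class is not drowned out by air
and soft tissue; cross-entropy stabilizes per-pixel calibration.  Both
terms are computed per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam
from .model import SliceSegmenter

_EPS_GDL = 1e-6
_EPS_CE = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 16
    epochs: int = 20
    lambda_dice: float = 1.0
    lambda_ce: float = 1.0
    seed: int = 0
    patience: int | None = None        # early stop on validation loss; None = off

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.lambda_dice < 0 or self.lambda_ce < 0:
            raise ValueError("loss weights must be >= 0")
        if self.lambda_dice == 0 and self.lambda_ce == 0:
            raise ValueError("at least one loss weight must be positive")


def _flatten(probs: np.ndarray, target_onehot: np.ndarray):
    if probs.shape != target_onehot.shape or probs.shape[-1] != 3:
        raise ValueError("probs and one-hot target must share a (..., 3) shape")
    return probs.reshape(-1, 3), target_onehot.reshape(-1, 3)


def generalized_dice_loss(probs: np.ndarray, target_onehot: np.ndarray,
                          with_grad: bool = False):
    """GDL = 1 - 2 * sum_c w_c sum_i p*g / (sum_c w_c sum_i (p+g) + eps),
    with w_c = 1 / (sum_i g_c + eps)^2.  Classes absent from the target
    contribute only through eps."""
    p, g = _flatten(probs, target_onehot)
    if not np.all((g == 0) | (g == 1)) or not np.allclose(g.sum(axis=1), 1):
        raise ValueError("target must be one-hot")
    w = 1.0 / (g.sum(axis=0) + _EPS_GDL) ** 2
    num = float(np.sum(w * np.sum(p * g, axis=0)))
    den = float(np.sum(w * np.sum(p + g, axis=0)) + _EPS_GDL)
    loss = 1.0 - 2.0 * num / den
    if not with_grad:
        return loss
    # d/dp: -2 (w_c g - (num/den) w_c) / den
    grad = (-2.0 * (w * g - (num / den) * w) / den).reshape(probs.shape)
    return loss, grad


def categorical_cross_entropy(probs: np.ndarray, target_onehot: np.ndarray,
                              with_grad: bool = False):
    """Mean per-pixel cross-entropy, probabilities clipped to [1e-7, 1]."""
    p, g = _flatten(probs, target_onehot)
    pc = np.clip(p, _EPS_CE, 1.0)
    n = p.shape[0]
    loss = float(-np.sum(g * np.log(pc)) / n)
    if not with_grad:
        return loss
    grad = np.where(p > _EPS_CE, -g / pc / n, 0.0).reshape(probs.shape)
    return loss, grad


def composite_loss(probs: np.ndarray, target_onehot: np.ndarray,
                   lambda_dice: float = 1.0, lambda_ce: float = 1.0,
                   with_grad: bool = False):
    """lambda_dice * GDL + lambda_ce * CE (and its gradient w.r.t. probs)."""
    if lambda_dice == 0 and lambda_ce == 0:
        raise ValueError("at least one loss weight must be positive")
    if not with_grad:
        gdl = generalized_dice_loss(probs, target_onehot) if lambda_dice else 0.0
        ce = categorical_cross_entropy(probs, target_onehot) if lambda_ce else 0.0
        return lambda_dice * gdl + lambda_ce * ce
    total, grad = 0.0, np.zeros_like(probs)
    if lambda_dice:
        gdl, ggdl = generalized_dice_loss(probs, target_onehot, with_grad=True)
        total += lambda_dice * gdl
        grad += lambda_dice * ggdl
    if lambda_ce:
        ce, gce = categorical_cross_entropy(probs, target_onehot, with_grad=True)
        total += lambda_ce * ce
        grad += lambda_ce * gce
    return total, grad


def one_hot(targets: np.ndarray) -> np.ndarray:
    return np.eye(3)[np.asarray(targets, dtype=np.intp)]


def _evaluate_batch(model, inputs, targets, cfg, batch_size=32):
    """Composite loss + per-class recall over a dataset, without gradients."""
    losses, weights = [], []
    correct = np.zeros(3)
    support = np.zeros(3)
    for i in range(0, len(inputs), batch_size):
        xb = inputs[i:i + batch_size]
        tb = targets[i:i + batch_size]
        probs = model.forward(xb)
        losses.append(composite_loss(probs, one_hot(tb), cfg.lambda_dice, cfg.lambda_ce))
        weights.append(len(xb))
        pred = np.argmax(probs, axis=-1)
        for c in range(3):
            mask = tb == c
            support[c] += mask.sum()
            correct[c] += (pred[mask] == c).sum()
    recall = np.divide(correct, support, out=np.full(3, np.nan), where=support > 0)
    return float(np.average(losses, weights=weights)), recall


def train(model: SliceSegmenter, train_data, cfg: TrainConfig, val_data=None):
    """Seeded shuffled mini-batch loop with Adam.

    ``train_data``/``val_data`` are (inputs (N, V, R, W), targets (N, Ro, Do))
    pairs.  Records per-epoch train/val composite loss and per-class
    validation recall; restores the best-validation weights at the end.
    Raises on non-finite loss (divergence guard).
    """
    inputs, targets = np.asarray(train_data[0]), np.asarray(train_data[1])
    if inputs.shape[1:] != tuple(model.cfg.input_shape):
        raise ValueError("training inputs do not match the model input shape")
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    history = []
    best = (np.inf, None)
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(inputs))
        epoch_losses, epoch_sizes = [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            probs = model.forward(inputs[idx])
            loss, dprobs = composite_loss(probs, one_hot(targets[idx]),
                                          cfg.lambda_dice, cfg.lambda_ce, with_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={loss}")
            opt.zero_grad()
            model.backward(dprobs)
            opt.step()
            epoch_losses.append(loss)
            epoch_sizes.append(len(idx))
        row = {"epoch": epoch,
               "train_loss": float(np.average(epoch_losses, weights=epoch_sizes))}
        if val_data is not None:
            val_loss, recall = _evaluate_batch(model, np.asarray(val_data[0]),
                                               np.asarray(val_data[1]), cfg)
            row.update(val_loss=val_loss, recall_air=float(recall[0]),
                       recall_soft=float(recall[1]), recall_bone=float(recall[2]))
            if val_loss < best[0]:
                best = (val_loss, [p.value.copy() for p in model.params])
                bad_epochs = 0
            else:
                bad_epochs += 1
        history.append(row)
        if cfg.patience is not None and bad_epochs > cfg.patience:
            break
    if best[1] is not None:
        for p, v in zip(model.params, best[1]):
            p.value[...] = v
    return model, history


def history_to_csv(history, path) -> None:
    import csv
    if not history:
        return
    keys = list(history[0].keys())
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)
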