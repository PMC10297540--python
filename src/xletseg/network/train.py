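"""Seeded Tversky-loss training loop for the compact U-Net."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..metrics import TverskyParams, dice
from .layers import Adam
from .unet import NetworkConfigError, TrainConfig, UNet, binarize


class DataError(ValueError):
    """Training data missing or inconsistent with the configuration."""


def _to_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    """Stack a list of (ChannelStack | HxWxC array, mask) into NCHW/N1HW."""
    if not dataset:
        raise DataError("empty dataset")
    xs, ys = [], []
    for stack, mask in dataset:
        arr = stack.channels if hasattr(stack, "channels") else np.asarray(stack)
        if arr.ndim != 3:
            raise DataError("each input must be H x W x C")
        xs.append(arr.transpose(2, 0, 1))
        ys.append(np.asarray(mask, dtype=np.float64)[None])
    return np.stack(xs), np.stack(ys)


def soft_tversky_grad(
    probs: np.ndarray, truth: np.ndarray, params: TverskyParams
) -> tuple[float, np.ndarray]:
    """Batch-pooled soft Tversky loss and its gradient w.r.t. the
    probability map.

    Soft counts are pooled over the whole batch, so every pixel's gradient
    shares one global denominator; with alpha > beta, missing true cyst
    pixels is penalized harder than raising false alarms.
    """
    t = truth
    tp = float(np.sum(probs * t))
    fn = float(np.sum((1.0 - probs) * t))
    fp = float(np.sum(probs * (1.0 - t)))
    num = tp + params.epsilon
    den = tp + params.alpha * fn + params.beta * fp + params.epsilon
    loss = 1.0 - num / den
    # d(den)/dp = t - alpha*t + beta*(1-t);  d(num)/dp = t
    dden = t - params.alpha * t + params.beta * (1.0 - t)
    dprobs = -(t * den - num * dden) / den**2
    return loss, dprobs


def train(
    model: UNet,
    train_set,
    cfg: TrainConfig,
    val_set=None,
) -> tuple[UNet, pd.DataFrame]:
    """Optimize the Tversky loss with Adam for ``cfg.epochs`` epochs.

    ``train_set``/``val_set`` are sequences of ``(ChannelStack, mask)``.
    Returns the model and a per-epoch history frame with train (and, when a
    validation set is given, validation) loss and Dice.  Fully seeded: the
    minibatch order derives from ``cfg.seed``.
    """
    X, Y = _to_arrays(train_set)
    if X.shape[1] != cfg.in_channels:
        raise NetworkConfigError(
            f"data has {X.shape[1]} channels, config expects {cfg.in_channels}"
        )
    Xv = Yv = None
    if val_set:
        Xv, Yv = _to_arrays(val_set)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = model.forward(X[idx])
            loss, dprobs = soft_tversky_grad(probs, Y[idx], cfg.tversky)
            model.backward(dprobs)
            opt.step(model.gradients())
            epoch_loss += loss * len(idx)
        row = {"epoch": epoch, "train_loss": epoch_loss / n}
        row["train_dice"] = _mean_dice(model, X, Y)
        if Xv is not None:
            probs_v = model.forward(Xv)
            row["val_loss"], _ = soft_tversky_grad(probs_v, Yv, cfg.tversky)
            row["val_dice"] = float(
                np.mean([dice(binarize(p[0]), Yv[i, 0] > 0.5)
                         for i, p in enumerate(probs_v)])
            )
        rows.append(row)
        if (
            cfg.stop_at_train_dice is not None
            and row["train_dice"] >= cfg.stop_at_train_dice
        ):
            break
    history = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["epoch", "train_loss", "train_dice"]
    )
    return model, history


def _mean_dice(model: UNet, X: np.ndarray, Y: np.ndarray) -> float:
    probs = model.forward(X)
    return float(
        np.mean([dice(binarize(p[0]), Y[i, 0] > 0.5) for i, p in enumerate(probs)])
    )
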