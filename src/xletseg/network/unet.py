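"""Compact channel-count-agnostic U-Net with optional attention bottleneck.

The encoder halves resolution at each of ``len(base_filters) - 1`` pooling
steps while the filter count grows; the decoder mirrors it with nearest-
neighbour upsampling and skip concatenations; a 1x1 convolution plus
sigmoid produces a single-channel probability map at input resolution.
With ``use_transformer_bottleneck`` a single self-attention block runs over
the coarsest feature grid, providing the global-context pathway of a
Trans-Unet at desk scale.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..metrics import TverskyParams
from .layers import (
    Conv1x1,
    Conv3x3,
    MaxPool2,
    ReLU,
    SelfAttention,
    Sigmoid,
    UpsampleNearest2,
)


class NetworkConfigError(ValueError):
    """Network configuration inconsistent with the input."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Defaults mirror the reference full-scale configuration — Tversky loss
    (alpha 0.8, beta 0.2), Adam at 1e-4, filter ladder (8, 16, 32, 64, 128),
    150 epochs.  The desk-scale experiments in this package override
    ``base_filters``, ``epochs`` and ``learning_rate`` (see the docs).
    """

    in_channels: int = 1
    base_filters: tuple[int, ...] = (8, 16, 32, 64, 128)
    learning_rate: float = 1e-4
    epochs: int = 150
    tversky: TverskyParams = field(default_factory=TverskyParams)
    batch_size: int = 8
    use_transformer_bottleneck: bool = False
    stop_at_train_dice: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_channels < 1:
            raise NetworkConfigError("in_channels must be >= 1")
        if len(self.base_filters) < 2:
            raise NetworkConfigError("need at least 2 filter stages")
        if any(b >= a for a, b in zip(self.base_filters[1:], self.base_filters)):
            raise NetworkConfigError("base_filters must be strictly increasing")
        if self.epochs < 0:
            raise NetworkConfigError("epochs must be nonnegative")
        if self.batch_size < 1:
            raise NetworkConfigError("batch_size must be >= 1")


class UNet:
    """Encoder–decoder segmentation network (see module docstring)."""

    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        self.n_stages = len(f)
        self.enc: list[tuple[Conv3x3, ReLU, Conv3x3, ReLU]] = []
        c_prev = cfg.in_channels
        for c_out in f:
            self.enc.append(
                (Conv3x3(c_prev, c_out, rng), ReLU(), Conv3x3(c_out, c_out, rng), ReLU())
            )
            c_prev = c_out
        self.pools = [MaxPool2() for _ in range(self.n_stages - 1)]
        self.attention = (
            SelfAttention(f[-1], rng) if cfg.use_transformer_bottleneck else None
        )
        self.ups = [UpsampleNearest2() for _ in range(self.n_stages - 1)]
        self.dec: list[tuple[Conv3x3, ReLU, Conv3x3, ReLU]] = []
        for i in reversed(range(self.n_stages - 1)):
            c_in = f[i + 1] + f[i]  # upsampled + skip
            self.dec.append(
                (Conv3x3(c_in, f[i], rng), ReLU(), Conv3x3(f[i], f[i], rng), ReLU())
            )
        self.head = Conv1x1(f[0], 1, rng)
        self.sigmoid = Sigmoid()

    # -- parameter access ---------------------------------------------------
    def _layers_with_params(self):
        for i, block in enumerate(self.enc):
            yield f"enc{i}a", block[0]
            yield f"enc{i}b", block[2]
        if self.attention is not None:
            yield "attn", self.attention
        for i, block in enumerate(self.dec):
            yield f"dec{i}a", block[0]
            yield f"dec{i}b", block[2]
        yield "head", self.head

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, layer in self._layers_with_params()
            for k, v in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{k}": v
            for name, layer in self._layers_with_params()
            for k, v in layer.grads.items()
        }

    def parameter_count(self) -> int:
        return sum(int(v.size) for v in self.parameters().values())

    def parameter_checksum(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.parameters()):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.parameters()[key]).tobytes())
        return h.hexdigest()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cfg.in_channels:
            raise NetworkConfigError(
                f"expected {self.cfg.in_channels} input channels, got {c}"
            )
        down = 2 ** (self.n_stages - 1)
        if h % down or w % down:
            raise NetworkConfigError(
                f"input size {h}x{w} not divisible by 2^{self.n_stages - 1}"
            )
        skips = []
        for i in range(self.n_stages):
            ca, ra, cb, rb = self.enc[i]
            x = rb.forward(cb.forward(ra.forward(ca.forward(x))))
            if i < self.n_stages - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        if self.attention is not None:
            x = self.attention.forward(x)
        self._skip_channels = []
        for i, block in enumerate(self.dec):
            x = self.ups[i].forward(x)
            skip = skips[-(i + 1)]
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([x, skip], axis=1)
            ca, ra, cb, rb = block
            x = rb.forward(cb.forward(ra.forward(ca.forward(x))))
        return self.sigmoid.forward(self.head.forward(x))

    def backward(self, dprobs: np.ndarray) -> None:
        dy = self.head.backward(self.sigmoid.backward(dprobs))
        dskips = []
        for i in reversed(range(len(self.dec))):
            ca, ra, cb, rb = self.dec[i]
            dy = ca.backward(ra.backward(cb.backward(rb.backward(dy))))
            n_up = dy.shape[1] - self._skip_channels[i]
            dskips.append(dy[:, n_up:])
            dy = self.ups[i].backward(dy[:, :n_up])
        if self.attention is not None:
            dy = self.attention.backward(dy)
        for i in reversed(range(self.n_stages)):
            if i < self.n_stages - 1:
                dy = self.pools[i].backward(dy)
                # dskips were collected coarsest-first, i.e. dskips[j]
                # matches encoder stage j
                dy = dy + dskips[i]
            ca, ra, cb, rb = self.enc[i]
            dy = ca.backward(ra.backward(cb.backward(rb.backward(dy))))


def build_network(cfg: TrainConfig, input_side: int | None = None) -> UNet:
    """Construct a seeded network; optionally validate the input size."""
    net = UNet(cfg)
    if input_side is not None:
        down = 2 ** (len(cfg.base_filters) - 1)
        if input_side % down:
            raise NetworkConfigError(
                f"input side {input_side} not divisible by {down}"
            )
    return net


def predict(model: UNet, stack) -> np.ndarray:
    """Probability map (H, W) in [0, 1] for one ChannelStack or HxWxC array."""
    arr = stack.channels if hasattr(stack, "channels") else np.asarray(stack)
    x = arr.transpose(2, 0, 1)[None]
    return model.forward(x)[0, 0]


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Element-wise threshold to a {0,1} mask."""
    return (np.asarray(probs) >= threshold).astype(np.uint8)


# -- serialization ----------------------------------------------------------

def save_model(path: str | Path, model: UNet) -> None:
    cfg = model.cfg
    header = {
        "in_channels": cfg.in_channels,
        "base_filters": list(cfg.base_filters),
        "learning_rate": cfg.learning_rate,
        "epochs": cfg.epochs,
        "tversky": {
            "alpha": cfg.tversky.alpha,
            "beta": cfg.tversky.beta,
            "epsilon": cfg.tversky.epsilon,
        },
        "batch_size": cfg.batch_size,
        "use_transformer_bottleneck": cfg.use_transformer_bottleneck,
        "seed": cfg.seed,
    }
    buf = io.BytesIO()
    np.savez(
        buf,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **model.parameters(),
    )
    Path(path).write_bytes(buf.getvalue())


def load_model(path: str | Path) -> UNet:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        cfg = TrainConfig(
            in_channels=header["in_channels"],
            base_filters=tuple(header["base_filters"]),
            learning_rate=header["learning_rate"],
            epochs=header["epochs"],
            tversky=TverskyParams(**header["tversky"]),
            batch_size=header["batch_size"],
            use_transformer_bottleneck=header["use_transformer_bottleneck"],
            seed=header["seed"],
        )
        model = UNet(cfg)
        params = model.parameters()
        for key in params:
            params[key][...] = data[key]
        return model
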