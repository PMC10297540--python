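"""Additive white Gaussian noise injection and the SNR / dataset protocol.

OCT devices that display B-scans in the log domain turn multiplicative
speckle into approximately additive noise, so robustness is probed by adding
white Gaussian noise directly to the stored image (which is treated as
already log-transformed).  ``sigma`` is quoted on the 0–255 8-bit intensity
scale (protocol default 80) and divided by 255 internally.  The dataset
protocol replaces a seeded random 70% of the images with their noisy
versions and keeps the remaining 30% clean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image import Image2D


@dataclass(frozen=True)
class NoiseSpec:
    """Noise-injection protocol parameters.

    ``sigma`` — Gaussian standard deviation on the 0–255 scale (default 80).
    ``fraction_noisy`` — fraction of the dataset replaced by noisy versions
    (default 0.7).
    """

    sigma: float = 80.0
    fraction_noisy: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0.0 <= self.fraction_noisy <= 1.0:
            raise ValueError("fraction_noisy must be in [0, 1]")


def add_awgn(
    image: Image2D,
    sigma: float,
    seed: int | np.random.Generator | None = None,
    clip: bool = True,
) -> Image2D | np.ndarray:
    """Add seeded i.i.d. Normal(0, (sigma/255)^2) noise on the [0, 1] scale.

    With ``clip=True`` (default) returns an :class:`Image2D` clipped to
    [0, 1]; with ``clip=False`` returns the raw noisy array (the additive
    model under which the SNR is defined).
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = image.pixels + rng.normal(0.0, sigma / 255.0, size=image.shape)
    if clip:
        return Image2D(np.clip(noisy, 0.0, 1.0))
    return noisy


def snr_db(clean: Image2D | np.ndarray, noisy: Image2D | np.ndarray) -> float:
    """Signal-to-noise ratio ``10 log10(||A||_F^2 / ||A - B||_F^2)`` in dB."""
    a = clean.pixels if isinstance(clean, Image2D) else np.asarray(clean, dtype=np.float64)
    b = noisy.pixels if isinstance(noisy, Image2D) else np.asarray(noisy, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    noise_power = float(np.sum((a - b) ** 2))
    if noise_power == 0.0:
        raise ZeroDivisionError("SNR undefined: images are identical")
    return 10.0 * float(np.log10(np.sum(a**2) / noise_power))


def noisify_dataset(
    images: Sequence[Image2D], spec: NoiseSpec
) -> tuple[list[Image2D], np.ndarray]:
    """Replace exactly ``round(fraction_noisy * n)`` images with AWGN
    versions, chosen seeded-uniform without replacement.

    Returns the new image list and a boolean flag array marking the noisy
    entries.
    """
    n = len(images)
    rng = np.random.default_rng(spec.seed)
    n_noisy = int(round(spec.fraction_noisy * n))
    chosen = rng.choice(n, size=n_noisy, replace=False) if n_noisy else np.array([], dtype=int)
    flags = np.zeros(n, dtype=bool)
    flags[chosen] = True
    out: list[Image2D] = []
    for i, img in enumerate(images):
        out.append(add_awgn(img, spec.sigma, seed=rng) if flags[i] else img)
    return out, flags
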