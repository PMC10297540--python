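"""Channel formation: turning sub-band pyramids into network input stacks.

A "two-channel" representation of an image holds (0) the low-pass partial
reconstruction — the smooth regional structure — and (1) the high-pass
partial reconstruction — edges and fine detail — of one transform, each
min–max normalized to [0, 1].  Three multi-transform combinations stack the
per-transform channels:

``combo4``
    low-pass of all four transforms: curvelet, contourlet, circlet, dtcwt.
``combo5``
    ``combo4`` plus the contourlet high-pass.
``combo5hh``
    high-pass of all four transforms plus the contourlet low-pass.

High-pass sub-bands can be soft-threshold denoised before reconstruction
(magnitude shrinkage; phase is preserved for complex bands).  The channel
order above is fixed so trained models are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Image2D
from .transforms import (
    SubbandPyramid,
    TransformSpec,
    default_spec,
    forward,
    inverse_array,
)

FORMATIONS = ("simple", "two_ch", "combo4", "combo5", "combo5hh")
COMBO_CHANNELS = {"combo4": 4, "combo5": 5, "combo5hh": 5, "two_ch": 2, "simple": 1}
#: fixed transform order for the combination formations
COMBO_ORDER = ("curvelet", "contourlet", "circlet", "dtcwt")


@dataclass(frozen=True)
class DenoiseSpec:
    """Soft-threshold denoising policy for high-pass sub-bands.

    ``threshold_rule='universal'`` estimates a per-band universal threshold
    from the band's noise level; ``'fixed'`` applies ``fixed_lambda``
    everywhere (required in that case).
    """

    enabled: bool = False
    threshold_rule: str = "universal"
    fixed_lambda: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_rule not in ("universal", "fixed"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.threshold_rule == "fixed":
            if self.fixed_lambda is None or self.fixed_lambda < 0:
                raise ValueError("fixed rule requires a nonnegative fixed_lambda")


@dataclass(frozen=True)
class ChannelStack:
    """H x W x C stack of [0, 1]-normalized channels with unique labels."""

    channels: np.ndarray
    formation: str
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("channels must be H x W x C")
        if self.formation not in FORMATIONS:
            raise ValueError(f"unknown formation {self.formation!r}")
        if arr.shape[2] != COMBO_CHANNELS[self.formation]:
            raise ValueError(
                f"{self.formation} expects {COMBO_CHANNELS[self.formation]} "
                f"channels, got {arr.shape[2]}"
            )
        if len(set(self.channel_labels)) != arr.shape[2]:
            raise ValueError("channel labels must be unique, one per channel")
        if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
            raise ValueError("channel values must lie in [0, 1]")
        arr.setflags(write=False)
        object.__setattr__(self, "channels", arr)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.channels.shape[2]


def soft_threshold(band: np.ndarray, lam: float) -> np.ndarray:
    """Shrinkage ``sign(x) * max(|x| - lam, 0)``; complex values shrink in
    magnitude with phase preserved."""
    if lam < 0:
        raise ValueError("threshold must be nonnegative")
    band = np.asarray(band)
    mag = np.abs(band)
    scale = np.where(mag > lam, (mag - lam) / np.where(mag > 0, mag, 1.0), 0.0)
    return band * scale


def estimate_threshold(band: np.ndarray) -> float:
    """Universal threshold ``sigma_hat * sqrt(2 ln N)`` with the robust MAD
    noise estimate ``sigma_hat = median(|band|) / 0.6745``."""
    band = np.asarray(band)
    n = band.size
    sigma = float(np.median(np.abs(band))) / 0.6745
    return sigma * float(np.sqrt(2.0 * np.log(n)))


def _denoise_pyramid(pyr: SubbandPyramid, denoise: DenoiseSpec) -> SubbandPyramid:
    if not denoise.enabled:
        return pyr

    def shrink(band: np.ndarray) -> np.ndarray:
        lam = (
            denoise.fixed_lambda
            if denoise.threshold_rule == "fixed"
            else estimate_threshold(band)
        )
        return soft_threshold(band, lam)

    return pyr.map_bands(shrink)


def lowpass_image(pyr: SubbandPyramid) -> np.ndarray:
    """Partial inverse with all detail bands zeroed, at full resolution."""
    return inverse_array(pyr.zero_details())


def highpass_image(
    pyr: SubbandPyramid, denoise: DenoiseSpec | None = None
) -> np.ndarray:
    """Partial inverse with the low-pass zeroed (detail bands soft-
    thresholded first when denoising is enabled), at full resolution."""
    denoise = denoise or DenoiseSpec()
    return inverse_array(_denoise_pyramid(pyr, denoise).zero_lowpass())


def normalize_channel(arr: np.ndarray) -> np.ndarray:
    """Min–max map onto [0, 1]; an (almost) constant channel maps to zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    # "constant" up to numerical dust (partial reconstructions of constant
    # images leave ~1e-13 residues that must not be stretched to [0, 1])
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def build_simple(image: Image2D) -> ChannelStack:
    """Single-channel stack: the image itself (the no-transform baseline)."""
    return ChannelStack(
        channels=image.pixels[:, :, None].copy(),
        formation="simple",
        channel_labels=("image",),
    )


def _lp_hp(
    image: Image2D,
    transform: str,
    spec: TransformSpec | None,
    denoise: DenoiseSpec | None,
) -> tuple[np.ndarray, np.ndarray]:
    spec = spec or default_spec(transform, image.height)
    pyr = forward(image, spec)
    # the edge channel is the magnitude of the high-pass reconstruction:
    # edges should read "bright" regardless of the sign of the step
    return (
        normalize_channel(lowpass_image(pyr)),
        normalize_channel(np.abs(highpass_image(pyr, denoise))),
    )


def build_two_channel(
    image: Image2D,
    transform: str,
    spec: TransformSpec | None = None,
    denoise: DenoiseSpec | None = None,
) -> ChannelStack:
    """Two-channel stack ``[{transform}_lp, {transform}_hp]``."""
    lp, hp = _lp_hp(image, transform, spec, denoise)
    return ChannelStack(
        channels=np.stack([lp, hp], axis=-1),
        formation="two_ch",
        channel_labels=(f"{transform}_lp", f"{transform}_hp"),
    )


def build_combo(
    image: Image2D,
    formation: str,
    specs: dict[str, TransformSpec] | None = None,
    denoise: DenoiseSpec | None = None,
) -> ChannelStack:
    """Multi-transform combination stack (``combo4``/``combo5``/``combo5hh``)."""
    if formation not in ("combo4", "combo5", "combo5hh"):
        raise ValueError(f"unknown combination formation {formation!r}")
    specs = specs or {}
    parts = {
        t: _lp_hp(image, t, specs.get(t), denoise) for t in COMBO_ORDER
    }
    if formation == "combo4":
        labels = tuple(f"{t}_lp" for t in COMBO_ORDER)
        channels = [parts[t][0] for t in COMBO_ORDER]
    elif formation == "combo5":
        labels = tuple(f"{t}_lp" for t in COMBO_ORDER) + ("contourlet_hp",)
        channels = [parts[t][0] for t in COMBO_ORDER] + [parts["contourlet"][1]]
    else:  # combo5hh
        labels = tuple(f"{t}_hp" for t in COMBO_ORDER) + ("contourlet_lp",)
        channels = [parts[t][1] for t in COMBO_ORDER] + [parts["contourlet"][0]]
    return ChannelStack(
        channels=np.stack(channels, axis=-1),
        formation=formation,
        channel_labels=labels,
    )


def build_formation(
    image: Image2D,
    name: str,
    specs: dict[str, TransformSpec] | None = None,
    denoise: DenoiseSpec | None = None,
) -> ChannelStack:
    """Build any named formation: ``simple``, ``{transform}2`` two-channel
    (e.g. ``contourlet2``) or a combination name."""
    if name == "simple":
        return build_simple(image)
    if name in ("combo4", "combo5", "combo5hh"):
        return build_combo(image, name, specs, denoise)
    if name.endswith("2") and name[:-1] in COMBO_ORDER:
        t = name[:-1]
        return build_two_channel(image, t, (specs or {}).get(t), denoise)
    raise ValueError(f"unknown formation {name!r}")


FORMATION_NAMES = (
    "simple",
    "curvelet2",
    "contourlet2",
    "circlet2",
    "dtcwt2",
    "combo4",
    "combo5",
    "combo5hh",
)
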