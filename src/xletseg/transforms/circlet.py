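"""Circlet transform: decomposition onto concentric ring-shaped frequency
bands.

The spectrum is split by ``n_rings`` raised-cosine radial windows (Euclidean
radius) that sum to one, giving one low-pass band and ``n_rings - 1`` ring
bands.  Because the windows form an amplitude partition of unity, the bands
sum back to the original image exactly — the inverse is a plain addition.
Ring bands respond to circular/annular patterns whose dominant radial
frequency falls inside the ring, which is the property that makes this
decomposition suited to roundish structures such as cysts.
"""

from __future__ import annotations

import numpy as np

from ..image import Image2D
from . import _windows as win
from .base import InversionError, SubbandPyramid, TransformSpec, _check_input


def circlet_forward(image: Image2D, spec: TransformSpec) -> SubbandPyramid:
    n = _check_input(image, spec, "circlet")
    windows = win.ring_windows(n, spec.n_rings)
    spectrum = np.fft.fft2(image.pixels, norm="ortho")
    bands = [np.fft.ifft2(w * spectrum, norm="ortho").real for w in windows]
    return SubbandPyramid(
        transform="circlet",
        lowpass=bands[0],
        levels=[bands[1:]],
        geometry={"side": n, "n_rings": spec.n_rings},
    )


def _circlet_inverse_array(pyr: SubbandPyramid) -> np.ndarray:
    n = pyr.geometry.get("side")
    if n is None or pyr.lowpass.shape != (n, n):
        raise InversionError("circlet geometry does not match band shapes")
    acc = pyr.lowpass.astype(np.float64).copy()
    for band in pyr.levels[0]:
        if band.shape != (n, n):
            raise InversionError("circlet band shape mismatch")
        acc += band.real
    return acc


def circlet_inverse(pyr: SubbandPyramid) -> Image2D:
    return Image2D(_circlet_inverse_array(pyr))
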