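"""Dual-tree-style complex oriented wavelet frame.

Each dyadic scale is split into exactly six complex oriented sub-bands with
orientation centres at 15, 45, 75, 105, 135 and 165 degrees (i.e. +/-15,
+/-45, +/-75 in the signed convention).  The bands are made analytic by
restricting their frequency support to one half-plane, which is what gives
complex coefficients whose *magnitudes* are nearly shift invariant while
their phase carries local position — the operative properties of the
dual-tree complex wavelet transform.

Construction: amplitude partition-of-unity radial (square-annulus) windows
times six angular windows times a half-plane factor.  Reconstruction adds
twice the real part of each analytic band (the conjugate half-plane term)
plus the decimated low-pass, and is exact to FFT round-off.
"""

from __future__ import annotations

import numpy as np

from ..image import Image2D
from . import _windows as win
from .base import InversionError, SubbandPyramid, TransformSpec, _check_input

N_ORIENTATIONS = 6
ORIENTATION_DEG = (15, 45, 75, 105, 135, 165)


def _band_windows(n: int, levels: int) -> tuple[list[list[np.ndarray]], np.ndarray]:
    details, low = win.dyadic_radial_windows(n, levels, energy=False)
    angular = win.angular_windows(n, N_ORIENTATIONS, energy=False)
    hp = win.halfplane_factor(n)
    per_level = []
    for i in range(levels):  # coarse -> fine
        radial = details[levels - 1 - i]
        per_level.append([radial * a * hp for a in angular])
    return per_level, low


def dtcwt_forward(image: Image2D, spec: TransformSpec) -> SubbandPyramid:
    n = _check_input(image, spec, "dtcwt")
    windows, low = _band_windows(n, spec.levels)
    spectrum = np.fft.fft2(image.pixels, norm="ortho")
    levels = [
        [np.fft.ifft2(w * spectrum, norm="ortho") for w in lvl] for lvl in windows
    ]
    m = max(2, n >> (spec.levels - 1))
    lowpass = np.fft.ifft2(win.spectral_crop(low * spectrum, m), norm="ortho").real
    return SubbandPyramid(
        transform="dtcwt",
        lowpass=lowpass,
        levels=levels,
        geometry={
            "side": n,
            "levels": spec.levels,
            "orientations_deg": list(ORIENTATION_DEG),
        },
    )


def _dtcwt_inverse_array(pyr: SubbandPyramid) -> np.ndarray:
    g = pyr.geometry
    try:
        n = int(g["side"])
        levels = int(g["levels"])
    except (KeyError, TypeError) as exc:
        raise InversionError("dtcwt geometry metadata incomplete") from exc
    if len(pyr.levels) != levels:
        raise InversionError("dtcwt geometry does not match level count")
    acc = np.zeros((n, n), dtype=np.float64)
    for lvl in pyr.levels:
        for band in lvl:
            if band.shape != (n, n):
                raise InversionError("dtcwt band shape mismatch")
            acc += 2.0 * np.asarray(band).real
    low_spec = win.spectral_embed(np.fft.fft2(pyr.lowpass, norm="ortho"), n)
    acc += np.fft.ifft2(low_spec, norm="ortho").real
    return acc


def dtcwt_inverse(pyr: SubbandPyramid) -> Image2D:
    return Image2D(_dtcwt_inverse_array(pyr))
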