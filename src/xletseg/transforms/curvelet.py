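"""Discrete curvelet transform as an FFT tight frame.

The frequency plane is tiled by square-annulus (concentric-square) dyadic
scale windows times angular wedge windows whose *squares* sum to one, so the
transform is a Parseval (tight) frame: total coefficient energy equals image
energy exactly, and the adjoint is the inverse.  Angular resolution doubles
every other scale from coarse to fine, the parabolic scaling that makes
curvelets sparse on curved edges.

Wedge windows pair each orientation with its antipode (they depend on
orientation modulo a half-turn), so for real images every coefficient band
is real — no complex handling is needed downstream.  Detail bands are kept
at full resolution; only the low-pass, whose spectral support is an exact
sub-grid, is decimated (by lossless spectral cropping).
"""

from __future__ import annotations

import numpy as np

from ..image import Image2D
from . import _windows as win
from .base import InversionError, SubbandPyramid, TransformSpec, _check_input


def _angle_counts(levels: int, angles_at_coarsest: int) -> list[int]:
    # coarse -> fine: A, A, 2A, 2A, 4A, ...
    return [angles_at_coarsest * 2 ** (i // 2) for i in range(levels)]


def _band_windows(n: int, spec: TransformSpec) -> tuple[list[list[np.ndarray]], np.ndarray]:
    details, low = win.dyadic_radial_windows(n, spec.levels, energy=True)
    counts = _angle_counts(spec.levels, spec.angles_at_coarsest)
    # details is fine -> coarse; build coarse -> fine level lists
    per_level = []
    for i, n_ang in enumerate(counts):  # i = 0 coarsest
        radial = details[spec.levels - 1 - i]
        angular = win.angular_windows(n, n_ang, energy=True)
        per_level.append([radial * a for a in angular])
    return per_level, low


def curvelet_forward(image: Image2D, spec: TransformSpec) -> SubbandPyramid:
    n = _check_input(image, spec, "curvelet")
    windows, low = _band_windows(n, spec)
    spectrum = np.fft.fft2(image.pixels, norm="ortho")
    levels = [
        [np.fft.ifft2(w * spectrum, norm="ortho").real for w in lvl]
        for lvl in windows
    ]
    m = max(2, n >> (spec.levels - 1))
    lowpass = np.fft.ifft2(win.spectral_crop(low * spectrum, m), norm="ortho").real
    return SubbandPyramid(
        transform="curvelet",
        lowpass=lowpass,
        levels=levels,
        geometry={
            "side": n,
            "levels": spec.levels,
            "angles_at_coarsest": spec.angles_at_coarsest,
            "angle_counts": _angle_counts(spec.levels, spec.angles_at_coarsest),
        },
    )


def _spec_from_geometry(pyr: SubbandPyramid) -> tuple[int, TransformSpec]:
    g = pyr.geometry
    try:
        n = int(g["side"])
        spec = TransformSpec(
            transform="curvelet",
            levels=int(g["levels"]),
            angles_at_coarsest=int(g["angles_at_coarsest"]),
        )
    except (KeyError, TypeError) as exc:
        raise InversionError("curvelet geometry metadata incomplete") from exc
    if len(pyr.levels) != spec.levels:
        raise InversionError("curvelet geometry does not match level count")
    return n, spec


def _curvelet_inverse_array(pyr: SubbandPyramid) -> np.ndarray:
    n, spec = _spec_from_geometry(pyr)
    windows, low = _band_windows(n, spec)
    acc = np.zeros((n, n), dtype=np.complex128)
    for lvl_windows, lvl_bands in zip(windows, pyr.levels):
        if len(lvl_windows) != len(lvl_bands):
            raise InversionError("curvelet geometry does not match band counts")
        for w, band in zip(lvl_windows, lvl_bands):
            if band.shape != (n, n):
                raise InversionError("curvelet band shape mismatch")
            acc += w * np.fft.fft2(band, norm="ortho")
    acc += low * win.spectral_embed(np.fft.fft2(pyr.lowpass, norm="ortho"), n)
    return np.fft.ifft2(acc, norm="ortho").real


def curvelet_inverse(pyr: SubbandPyramid) -> Image2D:
    return Image2D(_curvelet_inverse_array(pyr))


def coefficient_energy(pyr: SubbandPyramid) -> float:
    """Total squared coefficient magnitude, low-pass included.  Equals the
    image energy for this tight frame."""
    total = float(np.sum(np.abs(pyr.lowpass) ** 2))
    for lvl in pyr.levels:
        for band in lvl:
            total += float(np.sum(np.abs(band) ** 2))
    return total
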