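"""Contourlet transform: Laplacian pyramid + directional filter bank.

Stage 1 is a Laplacian pyramid built with the CDF 9/7 biorthogonal scaling
filters and periodic boundary handling; it is perfectly reconstructing by
construction (each level stores the exact prediction residual).  Stage 2
splits each band-pass residual into a power-of-two number of directional
wedge bands with an FFT directional filter bank whose angular windows form
an exact partition of unity, so the wedge bands of a level sum back to the
residual exactly.

Level ordering in the pyramid is coarse -> fine; the ``directions_per_level``
entry of the spec is indexed the same way (default ``[4, 8, 8...]``).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.ndimage import convolve1d

from ..image import Image2D
from . import _windows as win
from .base import InversionError, SubbandPyramid, TransformSpec, _check_input


@lru_cache(maxsize=1)
def _pyramid_filters() -> tuple[np.ndarray, np.ndarray]:
    """CDF 9/7 analysis low-pass (DC gain 1) and synthesis/interpolation
    low-pass (DC gain 2), trimmed to odd symmetric length for zero phase."""
    import pywt

    wav = pywt.Wavelet("bior4.4")

    def trim(f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=np.float64)
        nz = np.nonzero(np.abs(f) > 1e-14)[0]
        return f[nz[0] : nz[-1] + 1]

    h = trim(wav.dec_lo)
    g = trim(wav.rec_lo)
    return h / h.sum(), 2.0 * g / g.sum()


def _blur_down(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    low = convolve1d(convolve1d(x, h, axis=0, mode="wrap"), h, axis=1, mode="wrap")
    return low[::2, ::2]


def _up_predict(c: np.ndarray, g: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    up = np.zeros(shape, dtype=np.float64)
    up[::2, ::2] = c
    return convolve1d(convolve1d(up, g, axis=0, mode="wrap"), g, axis=1, mode="wrap")


def _dfb_split(residual: np.ndarray, n_dir: int) -> list[np.ndarray]:
    windows = win.angular_windows(residual.shape[0], n_dir, energy=False)
    spectrum = np.fft.fft2(residual, norm="ortho")
    return [np.fft.ifft2(w * spectrum, norm="ortho").real for w in windows]


def contourlet_forward(image: Image2D, spec: TransformSpec) -> SubbandPyramid:
    n = _check_input(image, spec, "contourlet")
    h, g = _pyramid_filters()
    residuals_fine_to_coarse: list[np.ndarray] = []
    current = image.pixels.astype(np.float64)
    for _ in range(spec.levels):
        c = _blur_down(current, h)
        residuals_fine_to_coarse.append(current - _up_predict(c, g, current.shape))
        current = c
    dirs = spec.directions_per_level  # coarse -> fine
    levels = [
        _dfb_split(res, n_dir)
        for res, n_dir in zip(residuals_fine_to_coarse[::-1], dirs)
    ]
    return SubbandPyramid(
        transform="contourlet",
        lowpass=current,
        levels=levels,
        geometry={
            "side": n,
            "levels": spec.levels,
            "directions_per_level": list(dirs),
        },
    )


def _contourlet_inverse_array(pyr: SubbandPyramid) -> np.ndarray:
    g_meta = pyr.geometry
    try:
        n = int(g_meta["side"])
        n_levels = int(g_meta["levels"])
        dirs = [int(d) for d in g_meta["directions_per_level"]]
    except (KeyError, TypeError) as exc:
        raise InversionError("contourlet geometry metadata incomplete") from exc
    if len(pyr.levels) != n_levels or len(dirs) != n_levels:
        raise InversionError("contourlet geometry does not match level count")
    _, g = _pyramid_filters()
    current = pyr.lowpass.astype(np.float64)
    # levels are coarse -> fine; rebuild from the coarsest
    for lvl, n_dir in zip(pyr.levels, dirs):
        if len(lvl) != n_dir:
            raise InversionError("contourlet geometry does not match band counts")
        residual = np.zeros_like(np.asarray(lvl[0], dtype=np.float64))
        for band in lvl:
            residual += np.asarray(band).real
        expected = (current.shape[0] * 2, current.shape[1] * 2)
        if residual.shape != expected:
            raise InversionError("contourlet band shape mismatch")
        current = residual + _up_predict(current, g, residual.shape)
    if current.shape != (n, n):
        raise InversionError("contourlet geometry side mismatch")
    return current


def contourlet_inverse(pyr: SubbandPyramid) -> Image2D:
    return Image2D(_contourlet_inverse_array(pyr))
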