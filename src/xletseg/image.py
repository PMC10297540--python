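"""2-D grayscale image container and geometry helpers.

Every transform in this package operates on square, power-of-two-sided
arrays (the filter-bank decimations require it).  :class:`Image2D` is a thin
validated wrapper around a float64 array on the internal ``[0, 1]`` intensity
scale; :func:`pad_to_pow2` embeds an arbitrary image into the smallest
enclosing power-of-two square and records the crop window so inversion can
restore the original frame transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class DimensionError(ValueError):
    """Raised when an image shape violates a transform precondition."""


def is_pow2(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class Image2D:
    """A finite, ``[0, 1]``-clamped grayscale image.

    Parameters
    ----------
    pixels:
        2-D real array.  Values are clamped to ``[0, 1]`` at construction;
        non-finite values raise ``ValueError``.
    """

    pixels: np.ndarray
    height: int = field(init=False)
    width: int = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise DimensionError(f"expected a 2-D array, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        arr = np.clip(arr, 0.0, 1.0)
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "height", arr.shape[0])
        object.__setattr__(self, "width", arr.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def require_square_pow2(self) -> None:
        if self.height != self.width:
            raise DimensionError(f"image must be square, got {self.shape}")
        if not is_pow2(self.height):
            raise DimensionError(
                f"side must be a power of two, got {self.height}"
            )


def next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1).bit_length())


def pad_to_pow2(arr: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Symmetrically zero-pad ``arr`` to a power-of-two square.

    Returns the padded array and the crop window ``(r0, r1, c0, c1)`` such
    that ``padded[r0:r1, c0:c1]`` recovers the original array.
    """
    h, w = arr.shape
    side = next_pow2(max(h, w))
    top = (side - h) // 2
    left = (side - w) // 2
    out = np.zeros((side, side), dtype=np.float64)
    out[top : top + h, left : left + w] = arr
    return out, (top, top + h, left, left + w)


def crop_window(arr: np.ndarray, window: tuple[int, int, int, int]) -> np.ndarray:
    r0, r1, c0, c1 = window
    return arr[r0:r1, c0:c1]


def load_image(path: str | Path) -> Image2D:
    """Read a grayscale PNG/TIFF (8- or 16-bit) onto the [0, 1] scale."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse RGB(A) to luminance
        raw = raw[..., :3].mean(axis=-1)
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        arr = raw.astype(np.float64) / scale
    else:
        arr = raw.astype(np.float64)
    return Image2D(arr)


def save_image(path: str | Path, image: Image2D | np.ndarray) -> None:
    """Write an image as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    arr = image.pixels if isinstance(image, Image2D) else np.asarray(image)
    arr = np.clip(arr, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))
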