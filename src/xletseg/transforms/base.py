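"""Shared pyramid container, transform spec, dispatch and serialization."""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from ..image import DimensionError, Image2D, is_pow2

TRANSFORMS = ("contourlet", "dtcwt", "curvelet", "circlet")


class ConfigurationError(ValueError):
    """Transform parameters inconsistent with the image size."""


class InversionError(ValueError):
    """Pyramid geometry metadata is missing or tampered."""


@dataclass(frozen=True)
class TransformSpec:
    """Decomposition parameters for one X-let family.

    Parameters
    ----------
    transform:
        One of ``contourlet``, ``dtcwt``, ``curvelet``, ``circlet``.
    levels:
        Number of dyadic scales (ignored by circlet, which is single-scale
        in rings).
    directions_per_level:
        Contourlet only — directional band count per level, coarse to fine;
        entries must be powers of two >= 2.
    angles_at_coarsest:
        Curvelet only — number of wedge-pair orientations at the coarsest
        detail scale; doubles every other scale toward the finest.
    n_rings:
        Circlet only — total radial bands including the low-pass.
    """

    transform: str
    levels: int = 3
    directions_per_level: tuple[int, ...] | None = None
    angles_at_coarsest: int = 8
    n_rings: int = 5

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.levels < 1:
            raise ConfigurationError("levels must be >= 1")
        if self.transform == "contourlet":
            dirs = self.directions_per_level
            if dirs is None:
                dirs = tuple([4] + [8] * (self.levels - 1))
                object.__setattr__(self, "directions_per_level", dirs)
            dirs = tuple(int(d) for d in dirs)
            object.__setattr__(self, "directions_per_level", dirs)
            if len(dirs) != self.levels:
                raise ConfigurationError(
                    "directions_per_level must have one entry per level"
                )
            for d in dirs:
                if d < 2 or (d & (d - 1)) != 0:
                    raise ConfigurationError(
                        f"direction counts must be powers of two >= 2, got {d}"
                    )
        if self.transform == "circlet" and self.n_rings < 2:
            raise ConfigurationError("n_rings must be >= 2")
        if self.transform == "curvelet" and self.angles_at_coarsest < 1:
            raise ConfigurationError("angles_at_coarsest must be >= 1")

    def validate_for_size(self, side: int) -> None:
        """No band may be decimated below 2 x 2."""
        if self.transform == "contourlet":
            if side >> self.levels < 2:
                raise ConfigurationError(
                    f"{self.levels} levels too deep for a {side}-px image"
                )
        elif self.transform in ("dtcwt", "curvelet"):
            if side >> (self.levels - 1) < 2:
                raise ConfigurationError(
                    f"{self.levels} levels too deep for a {side}-px image"
                )


def default_spec(transform: str, side: int) -> TransformSpec:
    """Decomposition depth suited to the image size: 3 dyadic levels, or 2
    for small (<= 64 px) images."""
    levels = 2 if side <= 64 else 3
    return TransformSpec(transform=transform, levels=levels)


@dataclass
class SubbandPyramid:
    """One low-pass band plus per-level lists of directional detail bands.

    ``levels`` is ordered coarse -> fine.  ``geometry`` carries everything
    needed for exact inversion (transform parameters, original side length,
    band shapes).  DTCWT detail bands are complex; all others are real.
    """

    transform: str
    lowpass: np.ndarray
    levels: list[list[np.ndarray]]
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if not self.levels:
            raise ValueError("pyramid must have at least one detail level")
        if not np.all(np.isfinite(self.lowpass)):
            raise ValueError("non-finite low-pass band")
        for lvl in self.levels:
            for band in lvl:
                if not np.all(np.isfinite(band)):
                    raise ValueError("non-finite detail band")
        if self.transform == "dtcwt":
            for lvl in self.levels:
                if len(lvl) != 6:
                    raise ValueError("dtcwt levels must hold exactly 6 bands")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def band_counts(self) -> list[int]:
        return [len(lvl) for lvl in self.levels]

    def map_bands(self, fn: Callable[[np.ndarray], np.ndarray]) -> "SubbandPyramid":
        """New pyramid with ``fn`` applied to every detail band."""
        new_levels = [[fn(b) for b in lvl] for lvl in self.levels]
        return SubbandPyramid(
            transform=self.transform,
            lowpass=self.lowpass.copy(),
            levels=new_levels,
            geometry=dict(self.geometry),
        )

    def zero_details(self) -> "SubbandPyramid":
        return self.map_bands(lambda b: np.zeros_like(b))

    def zero_lowpass(self) -> "SubbandPyramid":
        out = self.map_bands(lambda b: b.copy())
        out.lowpass = np.zeros_like(self.lowpass)
        return out


def _check_input(image: Image2D, spec: TransformSpec, transform: str) -> int:
    if spec.transform != transform:
        raise ConfigurationError(
            f"spec.transform={spec.transform!r}, expected {transform!r}"
        )
    image.require_square_pow2()
    spec.validate_for_size(image.height)
    return image.height


def forward(image: Image2D, spec: TransformSpec) -> SubbandPyramid:
    """Dispatch to the forward transform named by ``spec.transform``."""
    from . import circlet, contourlet, curvelet, dtcwt

    fn = {
        "contourlet": contourlet.contourlet_forward,
        "dtcwt": dtcwt.dtcwt_forward,
        "curvelet": curvelet.curvelet_forward,
        "circlet": circlet.circlet_forward,
    }[spec.transform]
    return fn(image, spec)


def inverse(pyr: SubbandPyramid) -> Image2D:
    """Dispatch to the inverse transform for ``pyr.transform``."""
    from . import circlet, contourlet, curvelet, dtcwt

    fn = {
        "contourlet": contourlet.contourlet_inverse,
        "dtcwt": dtcwt.dtcwt_inverse,
        "curvelet": curvelet.curvelet_inverse,
        "circlet": circlet.circlet_inverse,
    }[pyr.transform]
    return fn(pyr)


def inverse_array(pyr: SubbandPyramid) -> np.ndarray:
    """Inverse reconstruction without the [0, 1] clamp of :class:`Image2D`.

    Partial reconstructions (low-pass only / high-pass only) legitimately
    leave the unit interval; channel formation normalizes afterwards.
    """
    from . import circlet, contourlet, curvelet, dtcwt

    fn = {
        "contourlet": contourlet._contourlet_inverse_array,
        "dtcwt": dtcwt._dtcwt_inverse_array,
        "curvelet": curvelet._curvelet_inverse_array,
        "circlet": circlet._circlet_inverse_array,
    }[pyr.transform]
    return fn(pyr)


# ---------------------------------------------------------------------------
# serialization: one array per band plus a JSON geometry header
# ---------------------------------------------------------------------------

def save_pyramid(path: str | Path, pyr: SubbandPyramid) -> None:
    """Write a pyramid as an ``.xlt`` container (zip of ``.npy`` arrays with
    a JSON header), cacheable between CLI stages."""
    arrays: dict[str, np.ndarray] = {"lowpass": pyr.lowpass}
    for j, lvl in enumerate(pyr.levels):
        for k, band in enumerate(lvl):
            arrays[f"level{j}_band{k}"] = band
    header = {
        "transform": pyr.transform,
        "n_levels": pyr.n_levels,
        "band_counts": pyr.band_counts(),
        "geometry": _jsonable(pyr.geometry),
    }
    buf = io.BytesIO()
    np.savez(buf, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_pyramid(path: str | Path) -> SubbandPyramid:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["header"]).decode())
        levels = [
            [data[f"level{j}_band{k}"] for k in range(count)]
            for j, count in enumerate(header["band_counts"])
        ]
        return SubbandPyramid(
            transform=header["transform"],
            lowpass=data["lowpass"],
            levels=levels,
            geometry=header["geometry"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj
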