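"""Synthetic OCT-like B-scan phantoms with ground-truth cyst masks.

A phantom emulates the contrast structure a retinal B-scan presents to the
sub-band formations: a stack of horizontally layered bright bands with
smooth vertical undulation, multiplicative speckle-like texture, and dark
(hypo-reflective) elliptical cysts embedded in the thickest bright layer.
The mask is the exact union of the cyst ellipses.  The generator makes no
claim of clinical realism — it reproduces the low-pass shape / high-pass
boundary contrast that the channel formations exploit.

The module also provides the augmentation pipeline (rotation, shift, crop)
and SSIM-based redundancy filtering used to curate augmented datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .image import Image2D, is_pow2


class GenerationError(RuntimeError):
    """Raised when cysts cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry and texture parameters.

    ``cyst_intensity_drop`` is the fractional darkening inside a cyst
    relative to its host layer (1.0 — fully dark).  ``speckle_contrast`` is
    the relative standard deviation of the multiplicative texture field.
    """

    size: int = 128
    n_layers: int = 5
    cyst_count_range: tuple[int, int] = (1, 3)
    cyst_radius_range: tuple[int, int] = (3, 10)
    cyst_intensity_drop: float = 0.85
    speckle_contrast: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not is_pow2(self.size):
            raise ValueError("size must be a power of two")
        if self.n_layers < 3:
            raise ValueError("need at least 3 layers")
        lo, hi = self.cyst_count_range
        if lo > hi or lo < 0:
            raise ValueError("empty cyst count range")
        rlo, rhi = self.cyst_radius_range
        if rlo > rhi or rlo < 1:
            raise ValueError("empty cyst radius range")
        if rhi >= self.size / 4:
            raise ValueError("cyst radii must be < size/4")
        if not 0.0 < self.cyst_intensity_drop <= 1.0:
            raise ValueError("cyst_intensity_drop must be in (0, 1]")
        if self.speckle_contrast < 0:
            raise ValueError("speckle_contrast must be nonnegative")


def _ellipse_mask(
    size: int, cy: float, cx: float, a: float, b: float, phi: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[Image2D, np.ndarray]:
    """Return a deterministic (image, binary mask) pair for ``spec``.

    Raises :class:`GenerationError` if the requested cysts cannot be placed
    without overlap inside the bright band after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size

    # smooth per-column vertical undulation of the retina
    x = np.arange(n) / n
    undulation = np.zeros(n)
    for _ in range(3):
        amp = rng.uniform(0.005, 0.02) * n
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        undulation += amp * np.sin(2 * np.pi * freq * x + phase)

    # retina occupies the middle half; one deliberately thick interior
    # layer hosts the cysts, the rest split the remainder randomly
    top, bottom = 0.22 * n, 0.8 * n
    host = int(rng.integers(1, spec.n_layers - 1))
    host_frac = rng.uniform(0.4, 0.5)
    rest = rng.uniform(0.5, 1.5, size=spec.n_layers - 1)
    rest = rest / rest.sum() * (1.0 - host_frac)
    widths = np.insert(rest, host, host_frac)
    edges = np.concatenate([[0.0], np.cumsum(widths)])
    edges[-1] = 1.0
    brightness = rng.uniform(0.35, 0.95, size=spec.n_layers)
    brightness[host] = rng.uniform(0.75, 0.9)

    yy = np.arange(n)[:, None] - undulation[None, :]
    img = np.full((n, n), 0.05)
    band_region = np.zeros((n, n), dtype=bool)
    for k in range(spec.n_layers):
        r0 = top + edges[k] * (bottom - top)
        r1 = top + edges[k + 1] * (bottom - top)
        layer = (yy >= r0) & (yy < r1)
        img[layer] = brightness[k]
        if k == host:
            band_region = layer

    # place non-overlapping cysts fully inside the host band
    count = int(rng.integers(spec.cyst_count_range[0], spec.cyst_count_range[1] + 1))
    mask = np.zeros((n, n), dtype=bool)
    host_r0 = top + edges[host] * (bottom - top)
    host_r1 = top + edges[host + 1] * (bottom - top)
    for _ in range(count):
        placed = False
        for _attempt in range(200):
            a = rng.uniform(spec.cyst_radius_range[0], spec.cyst_radius_range[1])
            b = rng.uniform(spec.cyst_radius_range[0], spec.cyst_radius_range[1])
            phi = rng.uniform(0, np.pi)
            rmax = max(a, b)
            cx = rng.uniform(rmax + 1, n - rmax - 1)
            # band rows shift with the undulation; bound over the span
            c0 = max(0, int(cx - rmax) - 1)
            c1 = min(n, int(cx + rmax) + 2)
            r_lo = host_r0 + undulation[c0:c1].max()
            r_hi = host_r1 + undulation[c0:c1].min()
            if r_hi - r_lo < 2 * rmax + 2:
                continue
            cy = rng.uniform(r_lo + rmax + 1, r_hi - rmax - 1)
            ell = _ellipse_mask(n, cy, cx, a, b, phi)
            if not ell.any():
                continue
            if (ell & mask).any() or not np.all(band_region[ell]):
                continue
            mask |= ell
            placed = True
            break
        if not placed:
            raise GenerationError(
                "could not place all cysts without overlap inside the band"
            )
    img[mask] *= 1.0 - spec.cyst_intensity_drop

    if spec.speckle_contrast > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=1.0)
        texture /= max(texture.std(), 1e-12)
        img *= 1.0 + spec.speckle_contrast * texture

    return Image2D(np.clip(img, 0.0, 1.0)), mask.astype(np.uint8)


@dataclass
class PhantomDataset:
    """Phantom pairs with a seeded train/test split."""

    images: list[Image2D]
    masks: list[np.ndarray]
    train_indices: np.ndarray
    test_indices: np.ndarray

    def split(self, which: str) -> tuple[list[Image2D], list[np.ndarray]]:
        idx = self.train_indices if which == "train" else self.test_indices
        return [self.images[i] for i in idx], [self.masks[i] for i in idx]


def generate_dataset(
    n: int,
    spec: PhantomSpec,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> PhantomDataset:
    """Generate ``n`` phantom pairs and a seeded random split with exactly
    ``round(train_fraction * n)`` training items."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    images, masks = [], []
    for i in range(n):
        child_seed = int(children[i].generate_state(1)[0] % (2**31))
        img, msk = generate_phantom(replace(spec, seed=child_seed))
        images.append(img)
        masks.append(msk)
    split_rng = np.random.default_rng(children[n])
    order = split_rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return PhantomDataset(
        images=images,
        masks=masks,
        train_indices=np.sort(order[:n_train]),
        test_indices=np.sort(order[n_train:]),
    )


# ---------------------------------------------------------------------------
# augmentation and SSIM deduplication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentSpec:
    """Random rotation/shift/crop augmentation parameters."""

    rotation_deg_range: tuple[float, float] = (-15.0, 15.0)
    shift_px_range: tuple[float, float] = (-8.0, 8.0)
    crop_fraction_range: tuple[float, float] = (0.8, 1.0)
    n_augments_per_image: int = 4
    ssim_dedup_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.crop_fraction_range
        if not (0.5 < lo <= hi <= 1.0):
            raise ValueError("crop fractions must lie in (0.5, 1]")
        if not 0.0 < self.ssim_dedup_threshold < 1.0:
            raise ValueError("ssim threshold must lie in (0, 1)")
        if self.n_augments_per_image < 1:
            raise ValueError("need at least one augmentation per image")


def _transform_pair(
    image: np.ndarray,
    mask: np.ndarray,
    angle: float,
    shift: tuple[float, float],
    crop_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    img = image.astype(np.float64)
    msk = mask.astype(np.float64)
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant")
        msk = ndimage.rotate(msk, angle, reshape=False, order=1, mode="constant")
    if shift != (0.0, 0.0):
        img = ndimage.shift(img, shift, order=1, mode="constant")
        msk = ndimage.shift(msk, shift, order=1, mode="constant")
    if crop_fraction < 1.0:
        n = img.shape[0]
        side = max(2, int(round(crop_fraction * n)))
        r0 = (n - side) // 2
        img = resize(img[r0 : r0 + side, r0 : r0 + side], (n, n), order=1,
                     anti_aliasing=False)
        msk = resize(msk[r0 : r0 + side, r0 : r0 + side], (n, n), order=1,
                     anti_aliasing=False)
    return np.clip(img, 0.0, 1.0), (msk > 0.5).astype(np.uint8)


def augment(
    image: Image2D, mask: np.ndarray, spec: AugmentSpec
) -> list[tuple[Image2D, np.ndarray]]:
    """Seeded random rotation/shift/crop combinations applied identically to
    image and mask; masks are re-binarized after interpolation."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_augments_per_image):
        angle = rng.uniform(*spec.rotation_deg_range)
        shift = (rng.uniform(*spec.shift_px_range), rng.uniform(*spec.shift_px_range))
        frac = rng.uniform(*spec.crop_fraction_range)
        img, msk = _transform_pair(image.pixels, mask, angle, shift, frac)
        out.append((Image2D(img), msk))
    return out


def rigid_transform_pair(
    image: Image2D,
    mask: np.ndarray,
    angle: float = 0.0,
    shift: tuple[float, float] = (0.0, 0.0),
    crop_fraction: float = 1.0,
) -> tuple[Image2D, np.ndarray]:
    """Deterministic single rotation/shift/crop (exposed for testing and
    for scripted augmentation)."""
    img, msk = _transform_pair(image.pixels, mask, angle, shift, crop_fraction)
    return Image2D(img), msk


def ssim(a: Image2D, b: Image2D) -> float:
    """Structural similarity with a 7x7 Gaussian window on the unit
    dynamic range."""
    return float(
        structural_similarity(
            a.pixels,
            b.pixels,
            win_size=7,
            gaussian_weights=True,
            sigma=1.5,
            data_range=1.0,
        )
    )


def write_dataset(out_dir, dataset: PhantomDataset) -> None:
    """Write paired ``img_####.png`` / ``mask_####.png`` files plus a
    ``manifest.csv`` with the split labels."""
    import csv
    from pathlib import Path

    from .image import save_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train = set(int(i) for i in dataset.train_indices)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "image", "mask", "split"])
        for i, (img, msk) in enumerate(zip(dataset.images, dataset.masks)):
            img_name, msk_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
            save_image(out / img_name, img)
            save_image(out / msk_name, msk.astype(np.float64))
            writer.writerow([i, img_name, msk_name, "train" if i in train else "test"])


def load_dataset(in_dir) -> PhantomDataset:
    """Read a directory written by :func:`write_dataset` (or any grayscale
    image / binary-mask pairs listed in the same manifest layout)."""
    import csv
    from pathlib import Path

    from .image import load_image

    src = Path(in_dir)
    images, masks, train_idx, test_idx = [], [], [], []
    with open(src / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            i = len(images)
            images.append(load_image(src / row["image"]))
            masks.append((load_image(src / row["mask"]).pixels > 0.5).astype(np.uint8))
            (train_idx if row["split"] == "train" else test_idx).append(i)
    return PhantomDataset(
        images=images,
        masks=masks,
        train_indices=np.asarray(train_idx, dtype=int),
        test_indices=np.asarray(test_idx, dtype=int),
    )


def dedup_by_ssim(images: list[Image2D], threshold: float) -> list[int]:
    """Greedy scan in index order; drop an image iff its SSIM with any
    already-kept image exceeds ``threshold``.  Returns kept indices."""
    kept: list[int] = []
    for i, img in enumerate(images):
        if all(ssim(img, images[j]) <= threshold for j in kept):
            kept.append(i)
    return kept
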