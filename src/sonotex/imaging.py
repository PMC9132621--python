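"""Image loading, standardisation, pyramid decomposition and patch tiling.

The pipeline operates on square grayscale images with intensities in
``[0, 1]`` standardised to 256 x 256 pixels.  Each image is decomposed
into a five-level average-pooling pyramid (sides 256, 128, 64, 32, 16);
every level is then tiled into non-overlapping 16 x 16 patches, giving
256 + 64 + 16 + 4 + 1 = 341 patches per image.

The patch order is frozen — levels in order (original, pooled x2, x4,
x8, x16), row-major within a level — because downstream feature
selection reports column indices that are only meaningful under a fixed
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "DEFAULT_SIDE",
    "PATCH_SIDE",
    "PYRAMID_FACTORS",
    "Pyramid",
    "PatchSet",
    "load_image",
    "resize_to_standard",
    "average_pool",
    "build_pyramid",
    "extract_patches",
]

DEFAULT_SIDE = 256
PATCH_SIDE = 16
#: pooling-block side per pyramid level (level 0 is the original image)
PYRAMID_FACTORS = (1, 2, 4, 8, 16)

# ITU-R BT.601 luminance weights for colour -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def _validate_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite intensities")
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Read a raster image as a grayscale float array in ``[0, 1]``.

    Colour inputs are converted with BT.601 luminance weights; integer
    intensities are rescaled by the dtype maximum.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise OSError(f"could not read image file {path!s}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr[:, :, :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise OSError(f"unsupported image layout {arr.shape} in {path!s}")
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(raw).dtype).max)
        arr = arr.astype(np.float64) / scale
    else:
        arr = arr.astype(np.float64)
    return np.clip(_validate_gray(arr, f"image {path!s}"), 0.0, 1.0)


def resize_to_standard(img: np.ndarray, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Resize to ``side x side`` with bilinear interpolation.

    Anti-aliasing is applied only when downscaling.  ``side`` must be a
    positive multiple of the patch side so the tiling downstream stays
    exact.
    """
    img = _validate_gray(img)
    if side <= 0 or side % PATCH_SIDE != 0:
        raise ValueError(f"side must be a positive multiple of {PATCH_SIDE}, got {side}")
    if img.shape == (side, side):
        return img.copy()
    anti_alias = img.shape[0] > side or img.shape[1] > side
    out = _sk_resize(img, (side, side), order=1, anti_aliasing=anti_alias,
                     mode="reflect", preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def average_pool(img: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means: each output pixel is the arithmetic
    mean of its ``factor x factor`` source block."""
    img = _validate_gray(img)
    if factor < 1:
        raise ValueError(f"pooling factor must be >= 1, got {factor}")
    h, w = img.shape
    if h % factor or w % factor:
        raise ValueError(f"image shape {img.shape} not divisible by factor {factor}")
    if factor == 1:
        return img.copy()
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


@dataclass(frozen=True)
class Pyramid:
    """Five-level average-pooling pyramid of a standardised image."""

    levels: tuple[np.ndarray, ...]
    factors: tuple[int, ...] = PYRAMID_FACTORS

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.factors):
            raise ValueError("one level per factor required")


def build_pyramid(img: np.ndarray, side: int = DEFAULT_SIDE) -> Pyramid:
    """Decompose a ``side x side`` image by successive average pooling."""
    img = _validate_gray(img)
    if img.shape != (side, side):
        raise ValueError(f"expected a {side}x{side} image, got {img.shape}")
    levels = tuple(average_pool(img, f) for f in PYRAMID_FACTORS)
    return Pyramid(levels=levels)


@dataclass(frozen=True)
class PatchSet:
    """Ordered fixed-size patches from all pyramid levels.

    ``patches`` has shape ``(n, patch_side, patch_side)``; ``provenance``
    holds one ``(level, row_block, col_block)`` triple per patch.
    """

    patches: np.ndarray
    provenance: np.ndarray = field(repr=False)
    patch_side: int = PATCH_SIDE

    def __len__(self) -> int:
        return self.patches.shape[0]


def extract_patches(pyr: Pyramid, patch_side: int = PATCH_SIDE) -> PatchSet:
    """Tile every pyramid level into non-overlapping patches.

    Levels are traversed in pyramid order and each level row-major, so a
    standard 256-side pyramid yields per-level counts (256, 64, 16, 4, 1)
    and 341 patches in total; the last patch is the 16 x 16 coarsest
    level verbatim.
    """
    tiles = []
    prov = []
    for lvl, img in enumerate(pyr.levels):
        h, w = img.shape
        if h % patch_side or w % patch_side:
            raise ValueError(
                f"level {lvl} shape {img.shape} not divisible by patch side {patch_side}")
        nr, nc = h // patch_side, w // patch_side
        blocks = img.reshape(nr, patch_side, nc, patch_side).transpose(0, 2, 1, 3)
        tiles.append(blocks.reshape(nr * nc, patch_side, patch_side))
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        prov.append(np.column_stack(
            [np.full(nr * nc, lvl), rr.ravel(), cc.ravel()]))
    return PatchSet(patches=np.concatenate(tiles, axis=0),
                    provenance=np.concatenate(prov, axis=0),
                    patch_side=patch_side)


def export_patches(ps: PatchSet, out_dir: str | Path) -> list[Path]:
    """Debug helper: write every patch as an 8-bit PNG tile."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (patch, (lvl, r, c)) in enumerate(zip(ps.patches, ps.provenance), start=1):
        p = out_dir / f"patch_{i:03d}_L{lvl}_r{r}_c{c}.png"
        iio.imwrite(p, np.round(np.clip(patch, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths
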