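"""Conversion of raster expression images into scalar intensity grids.

Masked ISH expression images encode expression strength either as 8-bit
grayscale or through a "heat" colormap (black -> red -> yellow -> white).
This module recovers a scalar intensity grid in [0, 1] from either encoding,
filters out blank (all-black, i.e. no detected expression) images, and builds
the multi-resolution pyramid used for multi-scale texture featurization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ExpressionImage",
    "ScalePyramid",
    "DEFAULT_FACTORS",
    "heat_colormap",
    "heat_to_intensity",
    "intensity_to_heat_rgb",
    "is_blank",
    "downsample",
    "build_pyramid",
    "load_image",
]

#: Downsampling factors used by default for the multi-scale representation.
DEFAULT_FACTORS: tuple[int, ...] = (1, 2, 4, 8, 10, 16)


@dataclass(frozen=True)
class ExpressionImage:
    """A single masked expression image as a scalar intensity grid in [0, 1].

    Background pixels (outside the expression mask) are exactly zero.
    """

    gene_id: str
    image_id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be a 2-D grid, got ndim={px.ndim}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("pixel intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ScalePyramid:
    """Ordered multi-resolution levels of one image.

    ``levels`` is a tuple of ``(downsampling_factor, image)`` pairs with
    strictly increasing factors; the level at factor ``f`` has dimensions
    ``floor(H/f) x floor(W/f)``.
    """

    levels: tuple[tuple[int, ExpressionImage], ...]

    def __post_init__(self) -> None:
        factors = [f for f, _ in self.levels]
        if any(b <= a for a, b in zip(factors, factors[1:])):
            raise ValueError("pyramid factors must be strictly increasing")

    @property
    def factors(self) -> tuple[int, ...]:
        return tuple(f for f, _ in self.levels)

    def __iter__(self):
        return iter(self.levels)

    def __len__(self) -> int:
        return len(self.levels)


def heat_colormap(values: np.ndarray) -> np.ndarray:
    """Map intensities in [0, 1] to RGB along the heat path.

    The path runs black (0) -> red (1/3) -> yellow (2/3) -> white (1), the
    scale used by masked atlas expression images. Returns floats in
    [0, 1] with a trailing axis of length 3.
    """
    t = np.asarray(values, dtype=np.float64)
    r = np.clip(3.0 * t, 0.0, 1.0)
    g = np.clip(3.0 * t - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * t - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


#: 256-entry lookup table of the heat path, used for the colormap inverse.
HEAT_TABLE: np.ndarray = heat_colormap(np.arange(256) / 255.0)

_heat_tree: cKDTree | None = None


def _heat_lookup_tree() -> cKDTree:
    global _heat_tree
    if _heat_tree is None:
        _heat_tree = cKDTree(HEAT_TABLE)
    return _heat_tree


def intensity_to_heat_rgb(pixels: np.ndarray) -> np.ndarray:
    """Render an intensity grid as an 8-bit RGB heat image (exact inverse of
    :func:`heat_to_intensity` up to the 1/255 quantization)."""
    idx = np.round(np.asarray(pixels, dtype=np.float64) * 255.0).astype(np.intp)
    idx = np.clip(idx, 0, 255)
    return np.round(HEAT_TABLE[idx] * 255.0).astype(np.uint8)


def heat_to_intensity(
    rgb_image: np.ndarray, gene_id: str = "", image_id: str = ""
) -> ExpressionImage:
    """Invert the heat colormap: map each RGB pixel to a scalar intensity.

    Each pixel is assigned the position (in [0, 1]) of its nearest color
    along the 256-entry heat table; pure black maps to exactly 0 and the
    terminal color (white) to exactly 1. Nearest-neighbor lookup makes the
    inverse robust to mild compression noise.
    """
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an RGB raster of shape (H, W, 3)")
    rgb = rgb.astype(np.float64)
    if np.issubdtype(np.asarray(rgb_image).dtype, np.integer):
        rgb = rgb / 255.0
    flat = rgb.reshape(-1, 3)
    _, idx = _heat_lookup_tree().query(flat)
    intensity = (idx / 255.0).reshape(rgb.shape[:2])
    return ExpressionImage(gene_id, image_id, intensity)


def is_blank(image: ExpressionImage | np.ndarray, tol: float = 0.0) -> bool:
    """True iff every pixel is zero (no expression detected anywhere).

    ``tol`` allows a small epsilon for lossy-compressed inputs; the default
    is an exact-zero test, matching masked images whose background and
    undetected foreground are stored as pure black.
    """
    px = image.pixels if isinstance(image, ExpressionImage) else np.asarray(image)
    return bool(np.all(px <= tol))


def downsample(image: ExpressionImage, factor: int) -> ExpressionImage:
    """Block-average downsampling by an integer factor.

    Output pixel (i, j) is the arithmetic mean of the ``factor x factor``
    input block anchored at ``(i*factor, j*factor)``; trailing rows/columns
    that do not fill a complete block are dropped (no padding, avoiding
    edge bias in downstream texture statistics).
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    h, w = image.shape
    oh, ow = h // factor, w // factor
    if oh == 0 or ow == 0:
        raise ValueError(
            f"factor {factor} exceeds image dimensions {image.shape}"
        )
    if factor == 1:
        return image
    px = image.pixels[: oh * factor, : ow * factor]
    out = px.reshape(oh, factor, ow, factor).mean(axis=(1, 3))
    return ExpressionImage(image.gene_id, image.image_id, out)


def build_pyramid(
    image: ExpressionImage, factors: tuple[int, ...] = DEFAULT_FACTORS
) -> ScalePyramid:
    """Build the multi-resolution pyramid, one level per downsampling factor."""
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("all factors must be >= 1")
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise ValueError("factors must be sorted strictly ascending")
    return ScalePyramid(tuple((f, downsample(image, f)) for f in factors))


def load_image(
    path: str | Path,
    colormap: str = "auto",
    gene_id: str = "",
    image_id: str = "",
) -> ExpressionImage:
    """Read a PNG/JPEG raster and convert it to an intensity grid.

    ``colormap="gray"`` treats the file as 8-bit grayscale (identity map
    /255); ``"heat"`` inverts the heat colormap of an RGB file; ``"auto"``
    picks by channel count.
    """
    arr = iio.imread(Path(path))
    if image_id == "":
        image_id = Path(path).stem
    if colormap not in ("auto", "gray", "heat"):
        raise ValueError(f"unknown colormap {colormap!r}")
    if arr.ndim == 3 and arr.shape[-1] == 4:  # strip alpha if present
        arr = arr[..., :3]
    if colormap == "auto":
        colormap = "gray" if arr.ndim == 2 else "heat"
    if colormap == "gray":
        if arr.ndim == 3:
            raise ValueError(f"{path}: expected a grayscale raster")
        return ExpressionImage(gene_id, image_id, arr.astype(np.float64) / 255.0)
    return heat_to_intensity(arr, gene_id=gene_id, image_id=image_id)
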