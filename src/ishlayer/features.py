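"""Multi-scale local-binary-pattern (LBP) featurization of expression images.

Each pyramid level is summarized by the 256-bin histogram of LBP(8, 2)
codes over its interior pixels plus the level's raw mean intensity (257
features per level); level blocks are concatenated in pyramid order.

Conventions (fixed, so feature vectors are comparable across images):

* 8 neighbors sampled on a circle of radius 2 around each center pixel,
  neighbor 0 due east, proceeding counter-clockwise; off-grid sample points
  are bilinearly interpolated.
* Bit b of the code is 1 iff the sampled neighbor intensity is >= the
  center intensity (ties set the bit, so a constant image codes to 255);
  bits are packed with b = 0 as the least significant bit.
* Pixels closer than ceil(radius) to any border are excluded, so the
  histogram sums to the interior pixel count.
* Full 256-code histograms are kept; the "uniform" bin-merging variant is
  deliberately not supported (it degrades accuracy on expression images,
  whose statistics differ from natural photographs).
* Each histogram is max-scaled (divided by its largest bin) so every level
  block lies in [0, 1] with maximum exactly 1; the mean-intensity entry is
  kept raw (it is already in [0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import ExpressionImage, ScalePyramid

__all__ = [
    "LBPConfig",
    "FeatureVector",
    "BLOCK_SIZE",
    "lbp_code",
    "lbp_histogram",
    "image_features",
]

#: Features per pyramid level: 256 histogram bins + 1 mean intensity.
BLOCK_SIZE = 257


@dataclass(frozen=True)
class LBPConfig:
    """LBP sampling parameters: 8 neighbors on a circle of radius 2 by default."""

    n_neighbors: int = 8
    radius: float = 2.0
    uniform: bool = False

    def __post_init__(self) -> None:
        if self.n_neighbors != 8:
            raise ValueError(
                "n_neighbors must be 8 (256-bin code histograms require 8-bit codes)"
            )
        if not (self.radius > 0):
            raise ValueError("radius must be positive")
        if self.uniform:
            raise ValueError("uniform LBP bin merging is not supported")

    @property
    def margin(self) -> int:
        """Border width (pixels) excluded from code computation."""
        return math.ceil(self.radius)


def _neighbor_offsets(config: LBPConfig) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) offsets of the 8 sample points: east first, counter-clockwise.

    Rounded to 8 decimals so axis-aligned samples land exactly on grid
    points despite floating-point trig.
    """
    theta = 2.0 * np.pi * np.arange(config.n_neighbors) / config.n_neighbors
    dr = np.round(-config.radius * np.sin(theta), 8)
    dc = np.round(config.radius * np.cos(theta), 8)
    return dr, dc


def _as_pixels(image: ExpressionImage | np.ndarray) -> np.ndarray:
    if isinstance(image, ExpressionImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def _bilinear_at(px: np.ndarray, r: float, c: float) -> float:
    """Bilinear interpolation at a single (row, col) position."""
    r0, c0 = math.floor(r), math.floor(c)
    fr, fc = r - r0, c - c0
    r1 = r0 if fr == 0.0 else r0 + 1
    c1 = c0 if fc == 0.0 else c0 + 1
    top = (1.0 - fc) * px[r0, c0] + fc * px[r0, c1]
    bot = (1.0 - fc) * px[r1, c0] + fc * px[r1, c1]
    return (1.0 - fr) * top + fr * bot


def lbp_code(
    image: ExpressionImage | np.ndarray,
    center: tuple[int, int],
    config: LBPConfig = LBPConfig(),
) -> int:
    """LBP code (0..255) of a single interior pixel."""
    px = _as_pixels(image)
    m = config.margin
    i, j = center
    h, w = px.shape
    if i < m or j < m or i >= h - m or j >= w - m:
        raise ValueError(
            f"center {center} is within {m} pixels of the border of {px.shape}"
        )
    dr, dc = _neighbor_offsets(config)
    c0 = px[i, j]
    code = 0
    for b in range(config.n_neighbors):
        if _bilinear_at(px, i + dr[b], j + dc[b]) >= c0:
            code |= 1 << b
    return code


def _shifted_samples(px: np.ndarray, dr: float, dc: float, m: int) -> np.ndarray:
    """Bilinear samples at offset (dr, dc) from every interior pixel at once.

    For a fixed offset, the sampled grid is a convex combination of up to
    four integer-shifted copies of the image, so the whole interior can be
    interpolated with array slicing.
    """
    h, w = px.shape
    ih, iw = h - 2 * m, w - 2 * m
    r0, c0 = math.floor(dr), math.floor(dc)
    fr, fc = dr - r0, dc - c0

    def block(ro: int, co: int) -> np.ndarray:
        rs, cs = m + r0 + ro, m + c0 + co
        return px[rs : rs + ih, cs : cs + iw]

    if fr == 0.0 and fc == 0.0:
        return block(0, 0)
    if fr == 0.0:
        return (1.0 - fc) * block(0, 0) + fc * block(0, 1)
    if fc == 0.0:
        return (1.0 - fr) * block(0, 0) + fr * block(1, 0)
    top = (1.0 - fc) * block(0, 0) + fc * block(0, 1)
    bot = (1.0 - fc) * block(1, 0) + fc * block(1, 1)
    return (1.0 - fr) * top + fr * bot


def _code_grid(px: np.ndarray, config: LBPConfig) -> np.ndarray:
    """LBP codes of all interior pixels as an integer array."""
    m = config.margin
    h, w = px.shape
    center = px[m : h - m, m : w - m]
    codes = np.zeros(center.shape, dtype=np.int64)
    dr, dc = _neighbor_offsets(config)
    for b in range(config.n_neighbors):
        codes |= (_shifted_samples(px, dr[b], dc[b], m) >= center).astype(np.int64) << b
    return codes


def lbp_histogram(
    image: ExpressionImage | np.ndarray, config: LBPConfig = LBPConfig()
) -> np.ndarray:
    """256-bin histogram of LBP codes over interior pixels (raw counts).

    Bin c holds the number of interior pixels whose code equals c; the bins
    sum to the interior pixel count ``(H - 2m) * (W - 2m)``.
    """
    px = _as_pixels(image)
    m = config.margin
    h, w = px.shape
    if min(h, w) <= 2 * m + 1:
        raise ValueError(
            f"image of shape {px.shape} too small for LBP radius {config.radius}"
        )
    return np.bincount(_code_grid(px, config).ravel(), minlength=256)


def image_features(
    pyramid: ScalePyramid, config: LBPConfig = LBPConfig()
) -> "FeatureVector":
    """Concatenated per-level feature blocks of a scale pyramid.

    Per level: the 256-bin histogram divided by its maximal bin value
    (max-scaling to [0, 1]), then the level's raw mean intensity appended.
    """
    blocks = []
    for factor, level in pyramid:
        try:
            hist = lbp_histogram(level, config)
        except ValueError as exc:
            raise ValueError(f"pyramid level at factor {factor}: {exc}") from exc
        scaled = hist / hist.max()
        blocks.append(np.concatenate([scaled, [level.pixels.mean()]]))
    return FeatureVector(np.concatenate(blocks), pyramid.factors)


@dataclass(frozen=True)
class FeatureVector:
    """Concatenation over pyramid levels of (scaled LBP histogram, mean intensity)."""

    values: np.ndarray
    level_factors: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        expected = BLOCK_SIZE * len(self.level_factors)
        if vals.shape != (expected,):
            raise ValueError(
                f"expected {expected} features for {len(self.level_factors)} "
                f"levels, got shape {vals.shape}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "level_factors", tuple(self.level_factors))

    def __len__(self) -> int:
        return self.values.shape[0]

    def block(self, factor: int) -> np.ndarray:
        """The 257-entry block for one pyramid level."""
        i = self.level_factors.index(factor)
        return self.values[i * BLOCK_SIZE : (i + 1) * BLOCK_SIZE]
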