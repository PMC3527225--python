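"""Synthetic layered expression images for building and testing the pipeline.

Real layered tissue (the mouse cerebellum) presents a folded, finger-like
band structure in sagittal sections: an outer molecular band, a thin
Purkinje-cell stripe just beneath it, a wide granule-cell band with a dense
speckled texture, and a smooth white-matter core. Images of the same gene
come from different slices and different animals, so shape, size, position
and staining intensity all vary between them.

The generator emulates exactly those properties without attempting
anatomical realism. A star-shaped region with a sinusoidally folded
boundary ("fingers") stands in for the section outline; concentric radial
bands stand in for the layers; class-specific textures (thin bright stripe,
dense fine speckle, diffuse mottling, coarse smooth noise) provide the fine
structure that distinguishes layers whose coarse geometry overlaps.
Per-gene parameters fix a gene's geometry and staining level; per-image
affine jitter and independent texture resampling emulate slice-to-slice
and animal-to-animal variability, so pooling across a gene's images is
non-trivial. Background pixels outside the region mask are exactly zero,
matching masked expression images.

The ``negative`` class mixes three non-localized sub-patterns (uniform
diffuse staining, random blobs, near-blank), mimicking a randomly drawn
gene set with heterogeneous, non-layer-specific expression.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .preprocess import ExpressionImage, intensity_to_heat_rgb

__all__ = [
    "LayerClass",
    "POSITIVE_LAYERS",
    "GeneratorConfig",
    "ShapeParams",
    "TextureParams",
    "SyntheticGeneSpec",
    "ManifestRecord",
    "DatasetManifest",
    "random_spec",
    "generate_gene_images",
    "generate_dataset",
]


class LayerClass(str, Enum):
    """The five gene classes.

    ``molecular`` deliberately includes expression in the Purkinje stripe as
    well as the outer band: genes of the molecular layer mark Purkinje-cell
    dendritic arbors whose cell bodies sit in the Purkinje layer, so the two
    patterns co-occur.
    """

    PURKINJE = "purkinje"
    GRANULAR = "granular"
    MOLECULAR = "molecular"
    WHITE_MATTER = "white_matter"
    NEGATIVE = "negative"


#: The four layer classes (excludes the negative set).
POSITIVE_LAYERS: tuple[LayerClass, ...] = (
    LayerClass.PURKINJE,
    LayerClass.GRANULAR,
    LayerClass.MOLECULAR,
    LayerClass.WHITE_MATTER,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Rendering geometry and inter-image jitter amplitudes.

    Radial band boundaries are fractions of the (angle-dependent) outer
    radius, outside-in: the molecular band on top, the thin Purkinje stripe
    of width ``stripe_width`` starting at ``granular_frac``, the granule
    band down to ``core_frac``, white matter below; each gene additionally
    perturbs the boundaries (``ShapeParams.band_jitter``), as layer
    proportions vary between individuals. Jitter amplitudes are free
    parameters (inter-brain deformation magnitude is not a measured
    quantity); defaults are strong enough that images of one gene differ
    visibly in shape, size, position and intensity while remaining
    recognizable.
    """

    image_size: int = 256
    core_frac: float = 0.45
    granular_frac: float = 0.76
    stripe_width: float = 0.05
    translation_jitter: float = 0.08
    scale_jitter: float = 0.08
    rotation_jitter_deg: float = 12.0
    intensity_jitter: float = 0.20
    background_speckle_density: float = 0.03


@dataclass(frozen=True)
class ShapeParams:
    """Per-gene coarse geometry of the folded band region.

    ``band_jitter`` perturbs (core boundary, granule/stripe boundary,
    stripe width) relative to the :class:`GeneratorConfig` defaults.
    """

    finger_count: int = 3
    finger_amplitude: float = 0.16
    phase: float = 0.0
    base_radius: float = 0.62
    aspect: float = 0.9
    center: tuple[float, float] = (0.0, 0.0)
    band_jitter: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TextureParams:
    """Per-gene fine texture: speckle density and grain size (pixels)."""

    speckle_density: float = 0.5
    grain_size: float = 1.2


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Everything needed to reproduce one gene's image set byte-for-byte."""

    gene_id: str
    layer: LayerClass
    n_images: int
    shape_params: ShapeParams = field(default_factory=ShapeParams)
    intensity_level: float = 0.8
    texture_params: TextureParams = field(default_factory=TextureParams)
    rng_seed: int = 0
    negative_mode: str = "diffuse"
    #: Relative amplitude of faint secondary expression outside the gene's
    #: primary layer (expression is rarely perfectly exclusive: molecular
    #: genes often show some granule-band signal and vice versa).
    cross_expression: float = 0.0

    def __post_init__(self) -> None:
        if not (2 <= self.n_images <= 8):
            raise ValueError(f"n_images must be in [2, 8], got {self.n_images}")
        if not (0.0 < self.intensity_level <= 1.0):
            raise ValueError(
                f"intensity_level must be in (0, 1], got {self.intensity_level}"
            )
        if self.negative_mode not in ("diffuse", "blobs", "near_blank"):
            raise ValueError(f"unknown negative_mode {self.negative_mode!r}")


_NEGATIVE_MODES = ("diffuse", "blobs", "near_blank")


def random_spec(
    gene_id: str,
    layer: LayerClass,
    rng: np.random.Generator,
    n_images: int | None = None,
) -> SyntheticGeneSpec:
    """Draw a gene's parameters from the generator's default distributions."""
    layer = LayerClass(layer)
    if n_images is None:
        n_images = int(rng.integers(2, 9))
    shape = ShapeParams(
        finger_count=int(rng.integers(2, 5)),
        finger_amplitude=float(rng.uniform(0.10, 0.22)),
        phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        base_radius=float(rng.uniform(0.55, 0.70)),
        aspect=float(rng.uniform(0.80, 1.0)),
        center=(float(rng.uniform(-0.08, 0.08)), float(rng.uniform(-0.08, 0.08))),
        band_jitter=(
            float(rng.uniform(-0.05, 0.05)),
            float(rng.uniform(-0.05, 0.05)),
            float(rng.uniform(-0.015, 0.025)),
        ),
    )
    if layer is LayerClass.GRANULAR:
        texture = TextureParams(
            speckle_density=float(rng.uniform(0.45, 0.60)),
            grain_size=float(rng.uniform(1.0, 1.6)),
        )
    elif layer is LayerClass.MOLECULAR:
        # Deliberately overlaps the granule-band texture distribution: the
        # two classes then differ mainly in band position/width and in the
        # co-expressed Purkinje stripe, making them the hardest pair.
        texture = TextureParams(
            speckle_density=float(rng.uniform(0.35, 0.55)),
            grain_size=float(rng.uniform(0.8, 1.6)),
        )
    elif layer is LayerClass.WHITE_MATTER:
        texture = TextureParams(
            speckle_density=0.0, grain_size=float(rng.uniform(4.0, 7.0))
        )
    else:
        texture = TextureParams(
            speckle_density=float(rng.uniform(0.2, 0.5)),
            grain_size=float(rng.uniform(1.0, 3.0)),
        )
    mode = _NEGATIVE_MODES[int(rng.integers(3))]
    if layer is LayerClass.MOLECULAR:
        cross = float(rng.uniform(0.0, 0.45))
    elif layer is LayerClass.GRANULAR:
        cross = float(rng.uniform(0.0, 0.20))
    else:
        cross = 0.0
    return SyntheticGeneSpec(
        gene_id=gene_id,
        layer=layer,
        n_images=n_images,
        shape_params=shape,
        intensity_level=_intensity_distribution(rng),
        texture_params=texture,
        rng_seed=int(rng.integers(2**31)),
        negative_mode=mode,
        cross_expression=cross,
    )


def _intensity_distribution(rng: np.random.Generator) -> float:
    """Staining level of a gene; weakly expressed genes are common."""
    return float(rng.uniform(0.25, 1.0))


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], grain: float) -> np.ndarray:
    """Smooth random field normalized to [0, 1]."""
    g = gaussian_filter(rng.standard_normal(shape), max(grain, 1e-6))
    lo, hi = g.min(), g.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (g - lo) / (hi - lo)


def _speckle(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    grain: float,
) -> np.ndarray:
    """Sparse bright speckle: fraction ``density`` of pixels lit, grain-sized grains."""
    if density <= 0.0:
        return np.zeros(shape)
    noise = rng.random(shape)
    if grain > 0.5:
        noise = gaussian_filter(noise, grain / 2.0)
    thr = np.quantile(noise, 1.0 - density)
    brightness = 0.6 + 0.4 * rng.random(shape)
    return np.where(noise > thr, brightness, 0.0)


def _render_image(
    spec: SyntheticGeneSpec, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    n = cfg.image_size
    sp = spec.shape_params
    tp = spec.texture_params

    # Per-image jitter: different slice / different animal.
    ang = np.deg2rad(rng.uniform(-cfg.rotation_jitter_deg, cfg.rotation_jitter_deg))
    sj = 1.0 + rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)
    tx, ty = rng.uniform(-cfg.translation_jitter, cfg.translation_jitter, size=2)
    level = min(
        spec.intensity_level
        * (1.0 + rng.uniform(-cfg.intensity_jitter, cfg.intensity_jitter)),
        1.0,
    )

    ax = np.linspace(-1.0, 1.0, n)
    x, y = np.meshgrid(ax, ax)
    xc = x - sp.center[0] - tx
    yc = y - sp.center[1] - ty
    ca, sa = np.cos(ang), np.sin(ang)
    xr = (ca * xc + sa * yc) / sj
    yr = (-sa * xc + ca * yc) / (sj * sp.aspect)
    r = np.hypot(xr, yr)
    theta = np.arctan2(yr, xr)
    boundary = sp.base_radius * (
        1.0 + sp.finger_amplitude * np.cos(sp.finger_count * theta + sp.phase)
    )
    u = r / boundary
    mask = u <= 1.0

    jc, jg, jw = sp.band_jitter
    core_b = float(np.clip(cfg.core_frac + jc, 0.25, 0.65))
    gran_b = float(np.clip(cfg.granular_frac + jg, core_b + 0.10, 0.90))
    stripe_top = min(gran_b + max(cfg.stripe_width + jw, 0.02), 0.96)

    core = mask & (u < core_b)
    gran = mask & (u >= core_b) & (u < gran_b)
    stripe = mask & (u >= gran_b) & (u < stripe_top)
    outer = mask & (u >= stripe_top)

    img = np.zeros((n, n))
    layer = spec.layer
    if layer is LayerClass.PURKINJE:
        band = level * (0.75 + 0.25 * _smooth_noise(rng, (n, n), 1.5))
        img[stripe] = band[stripe]
    elif layer is LayerClass.GRANULAR:
        spk = _speckle(rng, (n, n), tp.speckle_density, tp.grain_size)
        band = level * (0.18 + 0.82 * spk)
        img[gran] = band[gran]
        if spec.cross_expression > 0:  # faint bleed into the outer band
            img[outer] = (spec.cross_expression * band)[outer]
    elif layer is LayerClass.MOLECULAR:
        spk = _speckle(rng, (n, n), tp.speckle_density, tp.grain_size)
        band = level * (0.18 + 0.82 * spk)
        img[outer] = band[outer]
        pk = 0.9 * level * (0.75 + 0.25 * _smooth_noise(rng, (n, n), 1.5))
        img[stripe] = pk[stripe]
        if spec.cross_expression > 0:  # faint granule-band co-expression
            img[gran] = (spec.cross_expression * band)[gran]
    elif layer is LayerClass.WHITE_MATTER:
        field_ = level * (0.30 + 0.70 * _smooth_noise(rng, (n, n), tp.grain_size))
        img[core] = field_[core]
    else:  # negative: non-localized sub-patterns
        if spec.negative_mode == "diffuse":
            # Smooth field with loose large-scale structure: random genes
            # are rarely uniform, their density drifts across the section.
            field_ = (
                0.35
                * level
                * _smooth_noise(rng, (n, n), 3.0)
                * (0.6 + 0.8 * _smooth_noise(rng, (n, n), n / 6.0))
            )
            img[mask] = field_[mask]
        elif spec.negative_mode == "blobs":
            n_blobs = int(rng.integers(3, 9))
            for _ in range(n_blobs):
                bu = rng.uniform(0.0, 0.8)
                bth = rng.uniform(0.0, 2.0 * np.pi)
                br = bu * sp.base_radius
                bx, by = br * np.cos(bth), br * np.sin(bth)
                sigma = rng.uniform(0.04, 0.12)
                img += (
                    0.9
                    * level
                    * np.exp(-((xr - bx) ** 2 + (yr - by) ** 2) / (2.0 * sigma**2))
                )
            img[~mask] = 0.0
        else:  # near_blank: a few isolated specks
            n_spots = int(rng.integers(10, 40))
            idx = np.flatnonzero(mask)
            if idx.size:
                chosen = rng.choice(idx, size=min(n_spots, idx.size), replace=False)
                flat = img.ravel()
                flat[chosen] = 0.5 * level

    # Patchy staining dropout: regions where the stain failed to develop,
    # attenuating expression by up to 70% (differs per image/slice).
    d = _smooth_noise(rng, (n, n), 8.0)
    img *= 1.0 - 0.7 * np.clip((d - 0.6) / 0.4, 0.0, 1.0)
    # Low-level nonspecific staining scattered within the section.
    bg = 0.4 * level * _speckle(rng, (n, n), cfg.background_speckle_density, 1.0)
    img = np.where(mask, np.maximum(img, bg), 0.0)
    np.clip(img, 0.0, 1.0, out=img)
    # Quantize to 8 bits so in-memory images match their PNG round trip.
    return np.round(img * 255.0) / 255.0


def generate_gene_images(
    spec: SyntheticGeneSpec, config: GeneratorConfig | None = None
) -> list[ExpressionImage]:
    """Render a gene's image set; identical spec + seed reproduce it exactly."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(spec.rng_seed)
    images = []
    for i in range(spec.n_images):
        px = _render_image(spec, cfg, rng)
        images.append(ExpressionImage(spec.gene_id, f"{spec.gene_id}_{i}", px))
    return images


@dataclass(frozen=True)
class ManifestRecord:
    gene_id: str
    label: LayerClass
    image_paths: tuple[str, ...]


@dataclass(frozen=True)
class DatasetManifest:
    """Mapping of genes to their layer labels and image files."""

    records: tuple[ManifestRecord, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if not rec.image_paths:
                raise ValueError(f"gene {rec.gene_id} has no images")
            for p in rec.image_paths:
                if p in seen:
                    raise ValueError(
                        f"image {p} belongs to both {seen[p]} and {rec.gene_id}"
                    )
                seen[p] = rec.gene_id

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rec.gene_id, rec.label.value, p)
            for rec in self.records
            for p in rec.image_paths
        ]
        return pd.DataFrame(rows, columns=["gene_id", "label", "image_path"])

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = self.to_frame()
        # Store paths relative to the manifest so the dataset is relocatable.
        df["image_path"] = [
            str(Path(p).relative_to(path.parent)) if Path(p).is_absolute() else p
            for p in df["image_path"]
        ]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path)
        records = []
        for gene_id, grp in df.groupby("gene_id", sort=False):
            labels = grp["label"].unique()
            if len(labels) != 1:
                raise ValueError(f"gene {gene_id} has conflicting labels {labels}")
            paths = tuple(
                str(p if Path(p).is_absolute() else path.parent / p)
                for p in grp["image_path"]
            )
            records.append(ManifestRecord(str(gene_id), LayerClass(labels[0]), paths))
        return cls(tuple(records))


def generate_dataset(
    n_per_class: int,
    n_negative: int,
    seed: int,
    out_dir: str | Path,
    colormap: str = "gray",
    config: GeneratorConfig | None = None,
) -> DatasetManifest:
    """Generate a labeled dataset of synthetic gene image sets on disk.

    Writes ``n_per_class`` genes for each of the four layer classes plus
    ``n_negative`` negative genes as 8-bit PNGs (grayscale or
    heat-colormapped RGB), along with ``manifest.csv``; fully reproducible
    under ``seed``.
    """
    if n_per_class < 5:
        raise ValueError(f"n_per_class must be >= 5, got {n_per_class}")
    if colormap not in ("gray", "heat"):
        raise ValueError(f"unknown colormap {colormap!r}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    specs: list[SyntheticGeneSpec] = []
    for layer in POSITIVE_LAYERS:
        for i in range(n_per_class):
            specs.append(random_spec(f"{layer.value}_{i:04d}", layer, rng))
    for i in range(n_negative):
        spec = random_spec(f"negative_{i:04d}", LayerClass.NEGATIVE, rng)
        # Deterministic cycle guarantees all three sub-patterns are present.
        specs.append(replace(spec, negative_mode=_NEGATIVE_MODES[i % 3]))

    records = []
    for spec in specs:
        paths = []
        for image in generate_gene_images(spec, cfg):
            fname = f"{image.image_id}.png"
            fpath = out_dir / fname
            if colormap == "gray":
                data = np.round(image.pixels * 255.0).astype(np.uint8)
            else:
                data = intensity_to_heat_rgb(image.pixels)
            iio.imwrite(fpath, data)
            paths.append(str(fpath))
        records.append(ManifestRecord(spec.gene_id, spec.layer, tuple(paths)))
    manifest = DatasetManifest(tuple(records))
    manifest.to_csv(out_dir / "manifest.csv")
    params = {
        "n_per_class": n_per_class,
        "n_negative": n_negative,
        "seed": seed,
        "colormap": colormap,
        "config": asdict(cfg),
    }
    (out_dir / "generation.json").write_text(json.dumps(params, indent=2))
    return manifest
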