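"""Featurized in-memory dataset: images -> multi-scale LBP feature matrix."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import BLOCK_SIZE, LBPConfig, image_features
from .preprocess import DEFAULT_FACTORS, ExpressionImage, build_pyramid, is_blank, load_image
from .synthetic_data import DatasetManifest, LayerClass

__all__ = ["FeaturizedDataset", "BinaryTask"]


@dataclass(frozen=True)
class BinaryTask:
    """One binary problem (positive layer vs a contrast set) over images."""

    X: np.ndarray  # (n_images, n_features)
    image_gene: np.ndarray  # gene id per image row
    genes: np.ndarray  # unique gene ids, manifest order
    y_gene: np.ndarray  # binary label per gene
    y_image: np.ndarray  # binary label per image

    @property
    def gene_labels(self) -> dict[str, int]:
        return dict(zip(self.genes.tolist(), self.y_gene.tolist()))


@dataclass(frozen=True)
class FeaturizedDataset:
    """Feature matrix for a labeled image collection, blank images excluded."""

    features: np.ndarray  # (n_images, 257 * n_levels)
    image_gene: np.ndarray
    image_ids: np.ndarray
    gene_labels: dict[str, LayerClass]
    level_factors: tuple[int, ...]
    lbp: LBPConfig = LBPConfig()

    @classmethod
    def from_images(
        cls,
        labeled_images: dict[str, tuple[LayerClass, list[ExpressionImage]]],
        factors: tuple[int, ...] = DEFAULT_FACTORS,
        lbp: LBPConfig = LBPConfig(),
    ) -> "FeaturizedDataset":
        rows, genes, ids = [], [], []
        labels: dict[str, LayerClass] = {}
        for gene_id, (label, images) in labeled_images.items():
            kept = 0
            for img in images:
                if is_blank(img):
                    continue
                fv = image_features(build_pyramid(img, factors), lbp)
                rows.append(fv.values)
                genes.append(gene_id)
                ids.append(img.image_id)
                kept += 1
            if kept:
                labels[gene_id] = LayerClass(label)
        if not rows:
            raise ValueError("no non-blank images in the dataset")
        return cls(
            features=np.vstack(rows),
            image_gene=np.asarray(genes),
            image_ids=np.asarray(ids),
            gene_labels=labels,
            level_factors=tuple(int(f) for f in factors),
            lbp=lbp,
        )

    @classmethod
    def from_manifest(
        cls,
        manifest: DatasetManifest,
        factors: tuple[int, ...] = DEFAULT_FACTORS,
        lbp: LBPConfig = LBPConfig(),
        colormap: str = "auto",
    ) -> "FeaturizedDataset":
        labeled = {
            rec.gene_id: (
                rec.label,
                [
                    load_image(p, colormap=colormap, gene_id=rec.gene_id)
                    for p in rec.image_paths
                ],
            )
            for rec in manifest.records
        }
        return cls.from_images(labeled, factors=factors, lbp=lbp)

    @property
    def n_images(self) -> int:
        return self.features.shape[0]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_labels)

    def select_levels(self, factors) -> "FeaturizedDataset":
        """Restrict to a subset of pyramid levels (column blocks)."""
        factors = tuple(int(f) for f in factors)
        cols = []
        for f in factors:
            i = self.level_factors.index(f)
            cols.extend(range(i * BLOCK_SIZE, (i + 1) * BLOCK_SIZE))
        return replace(
            self, features=self.features[:, cols], level_factors=factors
        )

    def binary_task(
        self,
        positive: LayerClass,
        negative: LayerClass = LayerClass.NEGATIVE,
    ) -> BinaryTask:
        positive, negative = LayerClass(positive), LayerClass(negative)
        if positive == negative:
            raise ValueError("positive and negative classes must differ")
        keep_genes = [
            g for g, lab in self.gene_labels.items() if lab in (positive, negative)
        ]
        keep_set = set(keep_genes)
        img_mask = np.asarray([g in keep_set for g in self.image_gene])
        genes = np.asarray(keep_genes)
        y_gene = np.asarray(
            [1 if self.gene_labels[g] == positive else 0 for g in keep_genes]
        )
        if y_gene.sum() == 0 or y_gene.sum() == len(y_gene):
            raise ValueError(
                f"task {positive.value} vs {negative.value} has a single class"
            )
        lab_of = dict(zip(genes.tolist(), y_gene.tolist()))
        image_gene = self.image_gene[img_mask]
        return BinaryTask(
            X=self.features[img_mask],
            image_gene=image_gene,
            genes=genes,
            y_gene=y_gene,
            y_image=np.asarray([lab_of[g] for g in image_gene]),
        )
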