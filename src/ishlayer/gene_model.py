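"""Gene-level decisions from pooled image scores.

A gene is a bag of 2-8 images; the label attaches to the bag (a
multiple-instance problem). Image scores are pooled into five order/moment
statistics — mean, median, and the top-1/2/3 scores — and a linear SVM over
the pooled vector makes the gene decision ("two-level" strategy). Genes
with fewer than three images duplicate their lowest score to fill the
top-k slots; mean and median are computed on the original, unduplicated
scores.

Three comparison strategies are also provided: ``mean_image_score``
(average pooling of image scores), ``mean_lbp_features`` (score the
per-gene averaged feature vector with an image-style classifier), and the
``single_image`` baseline (each image scored independently, evaluation
treating images as samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.svm import SVC

from .cv import make_cv_plan
from .image_model import ImageModel, _class_weights, ImageModelConfig
from .metrics import roc_auc

__all__ = [
    "Strategy",
    "GenePoolVector",
    "GenePrediction",
    "GeneModel",
    "GeneModelConfig",
    "POOL_STAT_NAMES",
    "pool_scores",
    "train_gene_classifier",
    "predict_gene",
    "rank_genome",
]

POOL_STAT_NAMES = ("mean", "median", "top1", "top2", "top3")


class Strategy(str, Enum):
    TWO_LEVEL = "two_level"
    MEAN_IMAGE_SCORE = "mean_image_score"
    MEAN_LBP_FEATURES = "mean_lbp_features"
    SINGLE_IMAGE = "single_image"


@dataclass(frozen=True)
class GenePoolVector:
    """The 5 pooled statistics (mean, median, top-1, top-2, top-3) of a gene."""

    gene_id: str
    stats: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.stats) != 5:
            raise ValueError("exactly 5 pooled statistics required")
        _, _, t1, t2, t3 = self.stats
        if not (t1 >= t2 >= t3):
            raise ValueError("top statistics must be non-increasing")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.stats, dtype=np.float64)


@dataclass(frozen=True)
class GenePrediction:
    gene_id: str
    score: float
    strategy: Strategy


def pool_scores(scores, gene_id: str = "") -> GenePoolVector:
    """Pool a gene's image scores into (mean, median, top-1, top-2, top-3).

    With fewer than three scores the lowest available value is duplicated
    until three values exist before taking the order statistics; mean and
    median use the original scores only. The median of an even count is the
    mean of the two central values.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("pool_scores requires at least one score")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    mean = float(s.mean())
    median = float(np.median(s))
    if s.size < 3:
        aug = np.concatenate([s, np.full(3 - s.size, s.min())])
    else:
        aug = s
    top = np.sort(aug)[::-1][:3]
    return GenePoolVector(
        gene_id=gene_id,
        stats=(mean, median, float(top[0]), float(top[1]), float(top[2])),
    )


#: Default regularization grid for the gene-level linear SVM.
DEFAULT_GENE_GRID_C: tuple[float, ...] = tuple(2.0**k for k in (-9, -6, -3, 0, 3))


@dataclass(frozen=True)
class GeneModelConfig:
    grid_C: tuple[float, ...] = DEFAULT_GENE_GRID_C
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid_C:
            raise ValueError("grid_C must be non-empty")


@dataclass(frozen=True)
class GeneModel:
    """Linear decision function over the 5 pooled statistics."""

    coef: np.ndarray
    intercept: float
    cost: float = 1.0

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=np.float64).ravel()
        if coef.shape != (5,):
            raise ValueError("gene model expects exactly 5 pooled features")
        object.__setattr__(self, "coef", coef)

    def score(self, pool: GenePoolVector | np.ndarray) -> float:
        v = pool.values if isinstance(pool, GenePoolVector) else np.asarray(pool)
        return float(self.coef @ v + self.intercept)

    def scores(self, pools) -> np.ndarray:
        return np.asarray([self.score(p) for p in pools])


def _pool_matrix(pools) -> np.ndarray:
    if isinstance(pools, np.ndarray):
        X = np.asarray(pools, dtype=np.float64)
    else:
        X = np.vstack([p.values if isinstance(p, GenePoolVector) else p for p in pools])
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError("pools must form an (n_genes, 5) matrix")
    return X


def train_gene_classifier(
    pools, labels, config: GeneModelConfig | None = None
) -> GeneModel:
    """Fit the gene-level linear SVM on pooled score vectors.

    Regularization C is tuned by stratified 5-fold cross-validation over
    genes (each gene is a single sample here, so grouping is automatic),
    maximizing AUC with ties broken toward smaller C; class costs are
    weighted by inverse class frequency, as for the image classifier.

    The five pooled statistics are standardized (per training fold) before
    fitting and the scaling is folded back into the returned linear
    coefficients, so the model remains a plain linear function of the raw
    pools while its regularization is invariant to the dynamic range of the
    image scores — pooled decision values can be nearly constant when the
    image classifier separates with a wide margin, and an unscaled linear
    SVM would degenerate there.
    """
    config = config or GeneModelConfig()
    X = _pool_matrix(pools)
    y = np.asarray(labels).astype(int)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must align with pools")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one gene per class")
    weights_cfg = ImageModelConfig()  # inverse-frequency weighting helper
    grid = sorted(float(c) for c in config.grid_C)
    n_folds = min(config.n_folds, int(min((y == 1).sum(), (y == 0).sum())))
    best_C, best_auc = grid[0], -np.inf

    def _scaled(A: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
        return (A - mu) / sd

    def _moments(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return A.mean(axis=0), np.maximum(A.std(axis=0), 1e-12)

    if n_folds >= 2 and len(grid) > 1:
        ids = [str(i) for i in range(len(y))]
        plan = make_cv_plan(ids, y, n_folds=n_folds, seed=config.seed)
        fold = plan.gene_folds(ids)
        for C in grid:
            aucs = []
            for f in range(n_folds):
                tr, va = fold != f, fold == f
                if len(np.unique(y[va])) < 2:
                    continue
                mu, sd = _moments(X[tr])
                svc = SVC(
                    kernel="linear", C=C, class_weight=_class_weights(y[tr], weights_cfg)
                )
                svc.fit(_scaled(X[tr], mu, sd), y[tr])
                aucs.append(
                    roc_auc(svc.decision_function(_scaled(X[va], mu, sd)), y[va])
                )
            auc = float(np.mean(aucs)) if aucs else -np.inf
            if auc > best_auc + 1e-12:
                best_auc, best_C = auc, C
    mu, sd = _moments(X)
    svc = SVC(kernel="linear", C=best_C, class_weight=_class_weights(y, weights_cfg))
    svc.fit(_scaled(X, mu, sd), y)
    w = svc.coef_.ravel() / sd
    b = float(svc.intercept_[0]) - float((svc.coef_.ravel() * mu / sd).sum())
    return GeneModel(coef=w, intercept=b, cost=best_C)


def predict_gene(
    strategy: Strategy | str,
    image_model: ImageModel,
    gene_model: GeneModel | None,
    image_features,
    gene_id: str = "",
):
    """Gene-level prediction for one gene's (non-blank) image features.

    ``image_features`` is an (n_images, n_features) matrix. For
    ``mean_lbp_features`` the ``image_model`` argument must be the model
    trained on per-gene averaged feature vectors. ``single_image`` returns
    one prediction per image (the baseline treats images as samples).
    """
    strategy = Strategy(strategy)
    F = np.atleast_2d(np.asarray(image_features, dtype=np.float64))
    if F.shape[0] == 0:
        raise ValueError(f"gene {gene_id!r} has no scorable images")
    if strategy is Strategy.MEAN_LBP_FEATURES:
        score = float(image_model.scores(F.mean(axis=0).reshape(1, -1))[0])
        return GenePrediction(gene_id, score, strategy)
    img_scores = image_model.scores(F)
    if strategy is Strategy.SINGLE_IMAGE:
        return [GenePrediction(gene_id, float(s), strategy) for s in img_scores]
    if strategy is Strategy.MEAN_IMAGE_SCORE:
        return GenePrediction(gene_id, float(img_scores.mean()), strategy)
    if gene_model is None:
        raise ValueError("two_level strategy requires a trained gene model")
    pooled = pool_scores(img_scores, gene_id=gene_id)
    return GenePrediction(gene_id, gene_model.score(pooled), strategy)


def rank_genome(
    image_model: ImageModel,
    gene_model: GeneModel | None,
    gene_features: dict[str, np.ndarray],
    strategy: Strategy | str = Strategy.TWO_LEVEL,
) -> list[GenePrediction]:
    """Score and sort unlabeled genes by descending confidence.

    ``gene_features`` maps gene_id to that gene's image feature matrix.
    Deterministic: ties are broken by gene_id. Genes without scorable
    images are excluded.
    """
    strategy = Strategy(strategy)
    if strategy is Strategy.SINGLE_IMAGE:
        raise ValueError("single_image is an image-level baseline, not a gene ranking")
    preds = []
    for gene_id in sorted(gene_features):
        F = np.atleast_2d(np.asarray(gene_features[gene_id]))
        if F.shape[0] == 0:
            continue
        preds.append(predict_gene(strategy, image_model, gene_model, F, gene_id))
    preds.sort(key=lambda p: (-p.score, p.gene_id))
    return preds
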