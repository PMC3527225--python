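"""Image-level classifier: RBF-kernel SVM with asymmetric class costs.

One binary classifier is trained per target layer on per-image feature
vectors. Class imbalance (few positive genes against a large negative set)
is absorbed by weighting misclassification costs inversely to class
frequency (c+ : c- = n- : n+). The classifier's signed decision value
(distance from the separating hyperplane) is the image's confidence score,
later pooled per gene.

Hyper-parameters (regularization C and RBF width gamma) are tuned by
gene-grouped cross-validated grid search maximizing AUC. Internally the
grid search precomputes the pairwise squared-distance matrix once per fold
and exponentiates it per gamma, which is mathematically identical to
fitting the RBF kernel directly but avoids recomputing feature dot
products for every grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVC

from .cv import make_cv_plan
from .features import FeatureVector
from .metrics import roc_auc

__all__ = [
    "ImageModelConfig",
    "ImageScore",
    "ImageModel",
    "DEFAULT_GRID_C",
    "DEFAULT_GRID_GAMMA",
    "train_image_classifier",
    "score_image",
    "grid_search_hyperparams",
]

#: Log-spaced default grids. The regularization grid spans weak to strong
#: penalties; the kernel-width grid spans widths suited to max-scaled
#: histogram features of a few hundred to a few thousand dimensions.
DEFAULT_GRID_C: tuple[float, ...] = tuple(2.0**k for k in range(-3, 8, 2))
DEFAULT_GRID_GAMMA: tuple[float, ...] = tuple(2.0**k for k in range(-9, 2, 2))


@dataclass(frozen=True)
class ImageModelConfig:
    """SVM parameters and tuning grids for the image-level classifier.

    ``cost_positive``/``cost_negative`` default to inverse class frequency
    when left as None. ``cost`` and ``kernel_width`` are the values used
    when training directly without grid search.
    """

    kernel: str = "rbf"
    cost: float = 1.0
    kernel_width: float | None = None
    cost_positive: float | None = None
    cost_negative: float | None = None
    grid_C: tuple[float, ...] = DEFAULT_GRID_C
    grid_gamma: tuple[float, ...] = DEFAULT_GRID_GAMMA
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the rbf kernel is supported")
        if not self.grid_C or not self.grid_gamma:
            raise ValueError("hyper-parameter grids must be non-empty")
        if self.cost <= 0:
            raise ValueError("cost must be positive")


@dataclass(frozen=True)
class ImageScore:
    """Signed decision value of one image; positive = predicted layer member."""

    gene_id: str
    image_id: str
    score: float


@dataclass
class ImageModel:
    """A trained image-level scorer."""

    svc: SVC
    n_features: int
    config: ImageModelConfig

    def scores(self, X) -> np.ndarray:
        """Signed decision values for rows of a feature matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training "
                f"length {self.n_features}"
            )
        return self.svc.decision_function(X)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=np.float64)
    else:
        rows = [
            f.values if isinstance(f, FeatureVector) else np.asarray(f, float)
            for f in features
        ]
        lengths = {r.shape[-1] for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"feature vectors have mismatched lengths {lengths}")
        X = np.vstack(rows)
    if X.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    return X


def _class_weights(y: np.ndarray, config: ImageModelConfig) -> dict[int, float]:
    """c+ : c- = n- : n+ unless both costs are given explicitly."""
    if config.cost_positive is not None and config.cost_negative is not None:
        return {1: config.cost_positive, 0: config.cost_negative}
    n = y.size
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    return {1: n / (2.0 * n_pos), 0: n / (2.0 * n_neg)}


def train_image_classifier(
    features, labels, config: ImageModelConfig | None = None
) -> ImageModel:
    """Fit the RBF SVM on labeled image feature vectors.

    ``labels`` are binary (1 = target layer). Uses ``config.cost`` and
    ``config.kernel_width`` as-is; tune them first with
    :func:`grid_search_hyperparams` when needed. ``kernel_width=None``
    falls back to sklearn's ``gamma="scale"`` heuristic.
    """
    config = config or ImageModelConfig()
    X = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must align with feature rows")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least one positive and one negative")
    gamma = config.kernel_width if config.kernel_width is not None else "scale"
    svc = SVC(
        kernel="rbf",
        C=config.cost,
        gamma=gamma,
        class_weight=_class_weights(y, config),
    )
    svc.fit(X, y)
    return ImageModel(svc=svc, n_features=X.shape[1], config=config)


def score_image(model: ImageModel, features) -> ImageScore:
    """Score one image with a trained model (deterministic)."""
    if isinstance(features, FeatureVector):
        gene_id, image_id, values = "", "", features.values
    else:
        gene_id, image_id, values = "", "", np.asarray(features, dtype=np.float64)
    score = float(model.scores(values.reshape(1, -1))[0])
    return ImageScore(gene_id=gene_id, image_id=image_id, score=score)


def _squared_distances(A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    D = euclidean_distances(A, B if B is not None else A, squared=True)
    np.maximum(D, 0.0, out=D)
    return D


def _fit_precomputed(K: np.ndarray, y: np.ndarray, C: float, weights) -> SVC:
    svc = SVC(kernel="precomputed", C=C, class_weight=weights)
    svc.fit(K, y)
    return svc


def _grid_search_precomputed(
    D: np.ndarray,
    y: np.ndarray,
    fold_of_sample: np.ndarray,
    grid_C,
    grid_gamma,
    config: ImageModelConfig,
) -> tuple[float, float, dict[tuple[float, float], np.ndarray]]:
    """Cross-validated AUC over the (C, gamma) grid on a precomputed
    squared-distance matrix.

    Returns the winning point (ties broken toward smaller C, then smaller
    gamma) plus, per grid point, the out-of-fold decision scores of every
    sample — each sample is scored exactly once, by the model whose
    training fold excluded it.
    """
    grid_C = sorted(float(c) for c in grid_C)
    grid_gamma = sorted(float(g) for g in grid_gamma)
    folds = np.unique(fold_of_sample)
    val_scores = {
        (C, g): np.full(y.shape, np.nan) for g in grid_gamma for C in grid_C
    }
    fold_auc = {key: [] for key in val_scores}
    for g in grid_gamma:
        K = np.exp(-g * D)
        for f in folds:
            va = fold_of_sample == f
            tr = ~va
            K_tr = K[np.ix_(tr, tr)]
            K_va = K[np.ix_(va, tr)]
            y_tr, y_va = y[tr], y[va]
            weights = _class_weights(y_tr, config)
            for C in grid_C:
                svc = _fit_precomputed(K_tr, y_tr, C, weights)
                s = svc.decision_function(K_va)
                val_scores[(C, g)][va] = s
                fold_auc[(C, g)].append(roc_auc(s, y_va))
    best = None
    best_auc = -np.inf
    for C in grid_C:  # C-major order implements the tie-break preference
        for g in grid_gamma:
            auc = float(np.mean(fold_auc[(C, g)]))
            if auc > best_auc + 1e-12:
                best_auc, best = auc, (C, g)
    assert best is not None
    return best[0], best[1], val_scores


def grid_search_hyperparams(
    features, labels, groups, config: ImageModelConfig | None = None
) -> tuple[float, float]:
    """Select (C, gamma) maximizing gene-grouped cross-validated AUC.

    ``groups`` are per-image gene ids; inner folds are assigned at the gene
    level so no gene straddles a split. Ties are broken toward smaller C
    (stronger regularization), then smaller gamma.
    """
    config = config or ImageModelConfig()
    X = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    groups = np.asarray([str(g) for g in groups])
    if not (X.shape[0] == y.size == groups.size):
        raise ValueError("features, labels and groups must align")
    genes, first = np.unique(groups, return_index=True)
    gene_y = []
    for g in genes:
        ys = np.unique(y[groups == g])
        if len(ys) != 1:
            raise ValueError(f"gene {g} carries multiple labels")
        gene_y.append(int(ys[0]))
    plan = make_cv_plan(genes, gene_y, n_folds=config.n_folds, seed=config.seed)
    fold_of_sample = plan.gene_folds(groups)
    D = _squared_distances(X)
    C, g, _ = _grid_search_precomputed(
        D, y, fold_of_sample, config.grid_C, config.grid_gamma, config
    )
    return C, g
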