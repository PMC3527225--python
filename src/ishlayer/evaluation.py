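"""Nested gene-grouped cross-validated evaluation of the layer classifiers.

The protocol mirrors a two-layer 5-fold cross-validation: outer folds
(gene-grouped, label-stratified) measure held-out performance; inner folds,
drawn only from each outer training set, tune the SVM hyper-parameters.
All splits are assigned at the gene level so no gene ever contributes
images to both sides of any split, and every split taken is recorded so
the absence of leakage can be audited after the fact.

For the two-level strategy the gene-level classifier is trained on
out-of-fold image scores: each training image is scored by an inner-fold
model that did not see its gene, so the pooled statistics fed to the gene
SVM have the same distribution as at test time. Because decision values
from different SVM fits are only comparable up to a per-model offset (the
bias term varies between fits, and can dominate when a fit separates with
a wide margin), scores are centered per scoring model — each inner fold's
validation scores around their mean, and the test images' scores around
theirs — before pooling. Centering subtracts one constant per model, so
within-model rankings are untouched.

Per-fold AUCs give the mean +/- sample standard deviation; ROC curves pool
the out-of-fold gene scores across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cv import CVPlan, make_cv_plan
from .datasets import BinaryTask, FeaturizedDataset
from .gene_model import (
    GeneModelConfig,
    Strategy,
    pool_scores,
    train_gene_classifier,
)
from .image_model import (
    ImageModelConfig,
    _class_weights,
    _fit_precomputed,
    _grid_search_precomputed,
    _squared_distances,
)
from .metrics import roc_auc, roc_points
from .synthetic_data import LayerClass, POSITIVE_LAYERS

__all__ = [
    "CVPlan",
    "make_cv_plan",
    "roc_auc",
    "roc_points",
    "EvalConfig",
    "EvalResult",
    "SplitRecord",
    "evaluate_layer",
    "one_vs_one_confusion",
    "resolution_ablation",
    "audit_no_leakage",
]

ALL_STRATEGIES = (
    Strategy.TWO_LEVEL,
    Strategy.MEAN_IMAGE_SCORE,
    Strategy.MEAN_LBP_FEATURES,
    Strategy.SINGLE_IMAGE,
)


@dataclass(frozen=True)
class EvalConfig:
    """Fold counts, seeds and tuning grids for the nested evaluation."""

    n_folds: int = 5
    inner_folds: int = 5
    seed: int = 0
    image_config: ImageModelConfig = field(default_factory=ImageModelConfig)
    gene_config: GeneModelConfig = field(default_factory=GeneModelConfig)

    def derived_seed(self, *salts: int) -> int:
        s = self.seed
        for salt in salts:
            s = (s * 100_003 + 7919 * (salt + 1)) % (2**31)
        return int(s)


@dataclass(frozen=True)
class SplitRecord:
    """One train/test split taken during the nested procedure (gene level)."""

    level: str  # "outer" or "inner"
    outer_fold: int
    fold: int
    train: frozenset[str]
    test: frozenset[str]


@dataclass(frozen=True)
class EvalResult:
    """Cross-validated performance of one strategy on one binary task."""

    layer: str
    strategy: Strategy
    per_fold_auc: tuple[float, ...]
    mean_auc: float
    auc_std: float
    roc_points: np.ndarray = field(repr=False)
    splits: tuple[SplitRecord, ...] = field(default=(), repr=False)


def _scores_by_gene(scores: np.ndarray, image_gene: np.ndarray, genes) -> list[np.ndarray]:
    by = {}
    for s, g in zip(scores, image_gene):
        by.setdefault(g, []).append(s)
    return [np.asarray(by[g]) for g in genes]


def _nested_binary_eval(
    task: BinaryTask,
    strategies: tuple[Strategy, ...],
    config: EvalConfig,
    layer_name: str,
) -> dict[Strategy, EvalResult]:
    genes, y_gene = task.genes, task.y_gene
    outer = make_cv_plan(genes, y_gene, n_folds=config.n_folds, seed=config.seed)
    gene_fold = outer.gene_folds(genes)
    img_fold = outer.gene_folds(task.image_gene)
    label_of = task.gene_labels

    splits: list[SplitRecord] = []
    fold_aucs: dict[Strategy, list[float]] = {s: [] for s in strategies}
    pooled_scores: dict[Strategy, list[np.ndarray]] = {s: [] for s in strategies}
    pooled_labels: dict[Strategy, list[np.ndarray]] = {s: [] for s in strategies}

    needs_image = any(s is not Strategy.MEAN_LBP_FEATURES for s in strategies)
    img_cfg = config.image_config

    for f in range(config.n_folds):
        splits.append(
            SplitRecord("outer", f, f, outer.train_genes(f), outer.test_genes(f))
        )
        tr_g_mask = gene_fold != f
        tr_genes, te_genes = genes[tr_g_mask], genes[~tr_g_mask]
        y_tr_gene, y_te_gene = y_gene[tr_g_mask], y_gene[~tr_g_mask]
        tr_i, te_i = img_fold != f, img_fold == f
        Xtr, Xte = task.X[tr_i], task.X[te_i]
        y_tr_img = task.y_image[tr_i]
        gene_tr_img, gene_te_img = task.image_gene[tr_i], task.image_gene[te_i]

        inner_seed = config.derived_seed(f, 1)
        inner = make_cv_plan(
            tr_genes, y_tr_gene, n_folds=config.inner_folds, seed=inner_seed
        )
        for fi in range(config.inner_folds):
            splits.append(
                SplitRecord("inner", f, fi, inner.train_genes(fi), inner.test_genes(fi))
            )

        if needs_image:
            D_tr = _squared_distances(Xtr)
            inner_fold_img = inner.gene_folds(gene_tr_img)
            C_best, g_best, val_scores = _grid_search_precomputed(
                D_tr, y_tr_img, inner_fold_img, img_cfg.grid_C, img_cfg.grid_gamma, img_cfg
            )
            oof_scores = val_scores[(C_best, g_best)].copy()
            # Center per scoring model: each inner fold was scored by a
            # different fit, whose decision values share an arbitrary offset.
            for fi in np.unique(inner_fold_img):
                m = inner_fold_img == fi
                oof_scores[m] -= oof_scores[m].mean()
            svc = _fit_precomputed(
                np.exp(-g_best * D_tr),
                y_tr_img,
                C_best,
                _class_weights(y_tr_img, img_cfg),
            )
            D_cross = _squared_distances(Xte, Xtr)
            s_te = svc.decision_function(np.exp(-g_best * D_cross))
            s_te_centered = s_te - s_te.mean()

        for strat in strategies:
            if strat is Strategy.TWO_LEVEL:
                tr_pools = [
                    pool_scores(s, gene_id=g)
                    for g, s in zip(
                        tr_genes, _scores_by_gene(oof_scores, gene_tr_img, tr_genes)
                    )
                ]
                gm = train_gene_classifier(
                    tr_pools,
                    y_tr_gene,
                    GeneModelConfig(
                        grid_C=config.gene_config.grid_C,
                        n_folds=config.gene_config.n_folds,
                        seed=config.derived_seed(f, 2),
                    ),
                )
                te_pools = [
                    pool_scores(s, gene_id=g)
                    for g, s in zip(
                        te_genes, _scores_by_gene(s_te_centered, gene_te_img, te_genes)
                    )
                ]
                scores = gm.scores(te_pools)
                labels = y_te_gene
            elif strat is Strategy.MEAN_IMAGE_SCORE:
                scores = np.asarray(
                    [s.mean() for s in _scores_by_gene(s_te, gene_te_img, te_genes)]
                )
                labels = y_te_gene
            elif strat is Strategy.SINGLE_IMAGE:
                scores = s_te
                labels = task.y_image[te_i]
            else:  # MEAN_LBP_FEATURES: classify per-gene averaged feature vectors
                Xg_tr = np.vstack(
                    [task.X[task.image_gene == g].mean(axis=0) for g in tr_genes]
                )
                Xg_te = np.vstack(
                    [task.X[task.image_gene == g].mean(axis=0) for g in te_genes]
                )
                Dg = _squared_distances(Xg_tr)
                Cg, gg, _ = _grid_search_precomputed(
                    Dg,
                    y_tr_gene,
                    inner.gene_folds(tr_genes),
                    img_cfg.grid_C,
                    img_cfg.grid_gamma,
                    img_cfg,
                )
                svc_g = _fit_precomputed(
                    np.exp(-gg * Dg), y_tr_gene, Cg, _class_weights(y_tr_gene, img_cfg)
                )
                scores = svc_g.decision_function(
                    np.exp(-gg * _squared_distances(Xg_te, Xg_tr))
                )
                labels = y_te_gene
            fold_aucs[strat].append(roc_auc(scores, labels))
            pooled_scores[strat].append(np.asarray(scores, dtype=np.float64))
            pooled_labels[strat].append(np.asarray(labels))

    split_tuple = tuple(splits)
    results = {}
    for strat in strategies:
        aucs = tuple(float(a) for a in fold_aucs[strat])
        all_s = np.concatenate(pooled_scores[strat])
        all_y = np.concatenate(pooled_labels[strat])
        results[strat] = EvalResult(
            layer=layer_name,
            strategy=strat,
            per_fold_auc=aucs,
            mean_auc=float(np.mean(aucs)),
            auc_std=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            roc_points=roc_points(all_s, all_y),
            splits=split_tuple,
        )
    return results


def evaluate_layer(
    dataset: FeaturizedDataset,
    layer: LayerClass | str,
    strategy=Strategy.TWO_LEVEL,
    config: EvalConfig | None = None,
    versus: LayerClass | str = LayerClass.NEGATIVE,
):
    """Nested cross-validated AUC of ``layer`` vs ``versus`` (default: the
    shared negative set).

    ``strategy`` may be a single strategy (returns one :class:`EvalResult`)
    or a sequence (returns a dict keyed by :class:`Strategy`; the image
    classifier and its scores are shared across strategies within each
    fold, so comparing strategies costs little more than one of them).
    """
    config = config or EvalConfig()
    single = isinstance(strategy, (str, Strategy))
    strategies = (
        (Strategy(strategy),) if single else tuple(Strategy(s) for s in strategy)
    )
    task = dataset.binary_task(LayerClass(layer), LayerClass(versus))
    results = _nested_binary_eval(task, strategies, config, LayerClass(layer).value)
    return results[strategies[0]] if single else results


def one_vs_one_confusion(
    dataset: FeaturizedDataset,
    layers: tuple[LayerClass, ...] | None = None,
    config: EvalConfig | None = None,
    strategy=Strategy.TWO_LEVEL,
) -> pd.DataFrame:
    """Upper-triangular matrix of pairwise errors, entry (i, j) = 1 - mean
    cross-validated AUC of the layer-i-vs-layer-j classifier."""
    if layers is None:
        layers = POSITIVE_LAYERS + (LayerClass.NEGATIVE,)
    layers = tuple(LayerClass(l) for l in layers)
    if len(layers) < 2:
        raise ValueError("need at least two layers")
    names = [l.value for l in layers]
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, li in enumerate(layers):
        for lj in layers[i + 1 :]:
            res = evaluate_layer(dataset, li, strategy, config, versus=lj)
            mat.loc[li.value, lj.value] = 1.0 - res.mean_auc
    return mat


def resolution_ablation(
    dataset: FeaturizedDataset,
    layer: LayerClass | str,
    factors: tuple[int, ...] | None = None,
    config: EvalConfig | None = None,
    strategy=Strategy.TWO_LEVEL,
    versus: LayerClass | str = LayerClass.NEGATIVE,
) -> dict:
    """AUC per single downsampling factor plus the multi-scale result.

    Returns ``{factor: EvalResult, ..., "multi": EvalResult}``.
    """
    factors = tuple(factors) if factors is not None else dataset.level_factors
    out = {}
    for f in factors:
        out[f] = evaluate_layer(
            dataset.select_levels((f,)), layer, strategy, config, versus
        )
    if len(factors) > 1:
        out["multi"] = evaluate_layer(
            dataset.select_levels(factors), layer, strategy, config, versus
        )
    else:
        out["multi"] = out[factors[0]]
    return out


def audit_no_leakage(splits) -> None:
    """Verify that no gene sits on both sides of any recorded split and that
    inner-fold genes never escape their outer training set.

    ``splits`` is an iterable of :class:`SplitRecord` (e.g. from
    ``EvalResult.splits``). Raises ``ValueError`` on any violation.
    """
    splits = list(splits)
    outer_train = {}
    outer_test = {}
    for rec in splits:
        if rec.train & rec.test:
            raise ValueError(
                f"{rec.level} split {rec.fold}: genes on both sides: "
                f"{sorted(rec.train & rec.test)[:5]}"
            )
        if rec.level == "outer":
            outer_train[rec.outer_fold] = rec.train
            outer_test[rec.outer_fold] = rec.test
    for rec in splits:
        if rec.level == "inner":
            if rec.outer_fold not in outer_train:
                raise ValueError("inner split without a matching outer split")
            universe = outer_train[rec.outer_fold]
            if not (rec.train <= universe and rec.test <= universe):
                raise ValueError(
                    f"inner split {rec.fold} of outer fold {rec.outer_fold} "
                    "uses genes outside the outer training set"
                )
            if rec.train & outer_test[rec.outer_fold]:
                raise ValueError(
                    f"outer-fold test genes leaked into inner training "
                    f"(outer fold {rec.outer_fold})"
                )
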