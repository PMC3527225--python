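"""Nested cross-validated evaluation, confusion and resolution ablation."""

import numpy as np
import pytest

from ishlayer import (
    EvalConfig,
    ExpressionImage,
    FeaturizedDataset,
    GeneModelConfig,
    ImageModelConfig,
    LayerClass,
    Strategy,
    audit_no_leakage,
    evaluate_layer,
    one_vs_one_confusion,
    resolution_ablation,
)
from ishlayer.evaluation import SplitRecord


def small_config(seed=0):
    return EvalConfig(
        n_folds=4,
        inner_folds=2,
        seed=seed,
        image_config=ImageModelConfig(grid_C=(1.0,), grid_gamma=(0.5,), n_folds=2),
        gene_config=GeneModelConfig(grid_C=(1.0,)),
    )


def cluster_dataset(n_pos=8, n_neg=8, sep=2.0, noise=0.3, seed=0, d=2):
    """Genes as Gaussian clusters in feature space; images jitter around
    their gene's center."""
    rng = np.random.default_rng(seed)
    rows, genes, ids, labels = [], [], [], {}
    for k in range(n_pos + n_neg):
        pos = k < n_pos
        gid = f"{'pos' if pos else 'neg'}{k}"
        center = rng.normal(sep if pos else -sep, 1.0, d)
        labels[gid] = LayerClass.PURKINJE if pos else LayerClass.NEGATIVE
        for i in range(int(rng.integers(2, 5))):
            rows.append(center + rng.normal(0, noise, d))
            genes.append(gid)
            ids.append(f"{gid}_{i}")
    return FeaturizedDataset(
        features=np.vstack(rows),
        image_gene=np.asarray(genes),
        image_ids=np.asarray(ids),
        gene_labels=labels,
        level_factors=(1,),
    )


class TestEvaluateLayer:
    def test_separable_dataset_reaches_auc_one_every_fold(self):
        ds = cluster_dataset(sep=3.0, noise=0.2)
        res = evaluate_layer(
            ds,
            LayerClass.PURKINJE,
            [Strategy.TWO_LEVEL, Strategy.MEAN_IMAGE_SCORE, Strategy.SINGLE_IMAGE],
            small_config(),
        )
        for r in res.values():
            assert r.per_fold_auc == (1.0,) * 4
            assert r.mean_auc == 1.0

    def test_result_invariants(self):
        ds = cluster_dataset(sep=0.8, noise=1.0, seed=3)
        r = evaluate_layer(ds, LayerClass.PURKINJE, Strategy.MEAN_IMAGE_SCORE, small_config())
        assert len(r.per_fold_auc) == 4
        assert min(r.per_fold_auc) <= r.mean_auc <= max(r.per_fold_auc)
        assert r.auc_std >= 0
        pts = r.roc_points
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_stable_across_seeds_within_fold_scatter(self):
        ds = cluster_dataset(n_pos=12, n_neg=12, sep=1.0, noise=1.2, seed=5)
        r0 = evaluate_layer(ds, LayerClass.PURKINJE, Strategy.MEAN_IMAGE_SCORE, small_config(0))
        r1 = evaluate_layer(ds, LayerClass.PURKINJE, Strategy.MEAN_IMAGE_SCORE, small_config(1))
        assert abs(r0.mean_auc - r1.mean_auc) <= 2 * (r0.auc_std + r1.auc_std)

    def test_no_gene_leaks_across_any_recorded_split(self):
        ds = cluster_dataset(seed=2)
        r = evaluate_layer(ds, LayerClass.PURKINJE, Strategy.TWO_LEVEL, small_config())
        audit_no_leakage(r.splits)
        # outer folds partition the genes
        outer = [s for s in r.splits if s.level == "outer"]
        assert len(outer) == 4
        all_test = frozenset().union(*(s.test for s in outer))
        assert all_test == frozenset(ds.gene_labels)


class TestOneVsOneConfusion:
    def test_separable_pair_has_near_zero_error(self):
        ds = cluster_dataset(sep=3.0, noise=0.2)
        # relabel negatives as a second layer to form a pairwise task
        labels = {
            g: (LayerClass.PURKINJE if v is LayerClass.PURKINJE else LayerClass.GRANULAR)
            for g, v in ds.gene_labels.items()
        }
        ds2 = FeaturizedDataset(
            ds.features, ds.image_gene, ds.image_ids, labels, ds.level_factors
        )
        mat = one_vs_one_confusion(
            ds2, (LayerClass.PURKINJE, LayerClass.GRANULAR), small_config()
        )
        assert mat.loc["purkinje", "granular"] == pytest.approx(0.0, abs=0.01)
        assert np.isnan(mat.loc["granular", "purkinje"])  # upper-triangular

    def test_layer_against_itself_rejected(self):
        ds = cluster_dataset()
        with pytest.raises(ValueError, match="must differ"):
            ds.binary_task(LayerClass.PURKINJE, LayerClass.PURKINJE)


def stripe_dataset(n_per_class=8, seed=0):
    """Thin 2-pixel stripes vs wide faint bands with identical coarse
    structure: each stripe sits inside one 16x16 block whose block mean
    equals the matching band's, so a factor-16 representation cannot
    distinguish the classes while factor 1 trivially can."""
    rng = np.random.default_rng(seed)
    labeled = {}
    for k in range(n_per_class):
        blocks = rng.integers(1, 7, size=2)  # shared by the matched pair
        for cls, label in (("stripe", LayerClass.PURKINJE), ("band", LayerClass.NEGATIVE)):
            gid = f"{cls}{k}"
            images = []
            for i, block in enumerate(blocks):
                px = np.zeros((128, 128))
                if cls == "stripe":
                    r = 16 * int(block) + 7
                    px[r : r + 2, :] = 0.8
                else:
                    px[16 * int(block) : 16 * int(block) + 16, :] = 0.1
                images.append(ExpressionImage(gid, f"{gid}_{i}", px))
            labeled[gid] = (label, images)
    return FeaturizedDataset.from_images(labeled, factors=(1, 16))


class TestResolutionAblation:
    def test_coarse_factor_averages_thin_stripes_away(self):
        ds = stripe_dataset()
        res = resolution_ablation(
            ds,
            LayerClass.PURKINJE,
            config=small_config(),
            strategy=Strategy.MEAN_IMAGE_SCORE,
        )
        assert res[1].mean_auc >= 0.95
        assert res[16].mean_auc <= 0.75  # coarse blocks are identical by design
        assert res["multi"].mean_auc >= res[16].mean_auc

    def test_single_factor_list_equals_direct_evaluation(self):
        ds = stripe_dataset(seed=7).select_levels((1,))
        direct = evaluate_layer(ds, LayerClass.PURKINJE, Strategy.MEAN_IMAGE_SCORE, small_config())
        via = resolution_ablation(
            ds,
            LayerClass.PURKINJE,
            factors=(1,),
            config=small_config(),
            strategy=Strategy.MEAN_IMAGE_SCORE,
        )
        assert via[1].mean_auc == direct.mean_auc
        assert via["multi"].mean_auc == direct.mean_auc


class TestLeakageAudit:
    def test_detects_gene_on_both_sides(self):
        bad = SplitRecord("outer", 0, 0, frozenset({"a", "b"}), frozenset({"b"}))
        with pytest.raises(ValueError, match="both sides"):
            audit_no_leakage([bad])

    def test_detects_inner_fold_escaping_outer_training_set(self):
        outer = SplitRecord("outer", 0, 0, frozenset({"a", "b"}), frozenset({"c"}))
        inner = SplitRecord("inner", 0, 0, frozenset({"a", "c"}), frozenset({"b"}))
        with pytest.raises(ValueError, match="outside the outer training set"):
            audit_no_leakage([outer, inner])
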