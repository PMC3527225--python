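"""Score pooling, the gene-level classifier and prediction strategies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ishlayer import (
    GeneModel,
    GenePoolVector,
    Strategy,
    pool_scores,
    predict_gene,
    rank_genome,
    train_gene_classifier,
    train_image_classifier,
)
from ishlayer.image_model import ImageModelConfig

finite_scores = st.lists(
    st.floats(-100, 100, allow_nan=False, allow_infinity=False), min_size=1, max_size=10
)


class TestPoolScores:
    def test_three_scores_direct_order_statistics(self):
        p = pool_scores([0.9, 0.5, 0.2])
        assert p.stats == pytest.approx((1.6 / 3, 0.5, 0.9, 0.5, 0.2))

    def test_single_score_duplicates_into_all_slots(self):
        assert pool_scores([0.4]).stats == (0.4, 0.4, 0.4, 0.4, 0.4)

    def test_two_scores_duplicate_lowest_for_top_k_only(self):
        # augmented set {1, 2, 1} for order statistics; mean/median on {1, 2}
        assert pool_scores([1.0, 2.0]).stats == (1.5, 1.5, 2.0, 1.0, 1.0)

    def test_empty_or_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pool_scores([])
        with pytest.raises(ValueError):
            pool_scores([1.0, np.nan])

    @settings(deadline=None, max_examples=60)
    @given(finite_scores)
    def test_permutation_invariant_and_bounded(self, scores):
        rng = np.random.default_rng(0)
        shuffled = list(scores)
        rng.shuffle(shuffled)
        a, b = pool_scores(scores), pool_scores(shuffled)
        assert a.stats == pytest.approx(b.stats)
        lo, hi = min(scores), max(scores)
        mean, median, t1, t2, t3 = a.stats
        assert lo - 1e-9 <= mean <= hi + 1e-9 and lo - 1e-9 <= median <= hi + 1e-9
        assert t1 >= t2 >= t3

    @settings(deadline=None, max_examples=60)
    @given(finite_scores, st.data())
    def test_monotone_in_every_input_score(self, scores, data):
        i = data.draw(st.integers(0, len(scores) - 1))
        bumped = list(scores)
        bumped[i] += data.draw(st.floats(0.001, 10))
        before = np.asarray(pool_scores(scores).stats)
        after = np.asarray(pool_scores(bumped).stats)
        assert np.all(after >= before - 1e-9)

    def test_duplication_is_noop_for_three_or_more(self):
        scores = [3.0, -1.0, 0.5, 2.0]
        p = pool_scores(scores)
        assert (p.stats[2], p.stats[3], p.stats[4]) == (3.0, 2.0, 0.5)

    def test_pool_vector_invariant_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            GenePoolVector("g", (0.0, 0.0, 1.0, 2.0, 0.0))


class TestGeneClassifier:
    def test_separable_pools_reach_perfect_held_in_auc(self):
        rng = np.random.default_rng(0)
        pos = [pool_scores(rng.normal(2, 0.5, 4)) for _ in range(10)]
        neg = [pool_scores(rng.normal(-2, 0.5, 4)) for _ in range(10)]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        gm = train_gene_classifier(pos + neg, y)
        s = gm.scores(pos + neg)
        assert np.all(s[:10] > s[10:].max())

    def test_permuted_labels_give_chance_auc(self):
        from ishlayer import roc_auc

        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(20):
            pools = [pool_scores(rng.normal(0, 1, 4)) for _ in range(30)]
            y = np.r_[np.ones(15, int), np.zeros(15, int)]
            rng.shuffle(y)
            gm = train_gene_classifier(pools[:20], y[:20])
            if y[20:].min() == y[20:].max():
                continue
            aucs.append(roc_auc(gm.scores(pools[20:]), y[20:]))
        assert 0.3 < np.mean(aucs) < 0.7

    def test_single_class_rejected(self):
        pools = [pool_scores([0.1]), pool_scores([0.2])]
        with pytest.raises(ValueError, match="per class"):
            train_gene_classifier(pools, [1, 1])


@pytest.fixture(scope="module")
def toy_image_model():
    rng = np.random.default_rng(0)
    X = np.r_[rng.normal(2, 0.4, (20, 2)), rng.normal(-2, 0.4, (20, 2))]
    y = np.r_[np.ones(20, int), np.zeros(20, int)]
    return train_image_classifier(X, y, ImageModelConfig(cost=1.0, kernel_width=0.5))


class TestPredictGene:
    def test_identical_images_mean_score_equals_each_image(self, toy_image_model):
        F = np.tile(np.array([[2.0, 2.1]]), (3, 1))
        pred = predict_gene(Strategy.MEAN_IMAGE_SCORE, toy_image_model, None, F, "g")
        single = toy_image_model.scores(F[:1])[0]
        assert pred.score == pytest.approx(single)

    def test_two_level_on_single_image_collapses_to_its_score(self, toy_image_model):
        gm = GeneModel(coef=np.array([0.2] * 5), intercept=0.0)
        F = np.array([[1.8, 2.2]])
        s = toy_image_model.scores(F)[0]
        pred = predict_gene(Strategy.TWO_LEVEL, toy_image_model, gm, F, "g")
        assert pred.score == pytest.approx(s)  # all 5 pooled stats equal s

    def test_mean_pooling_gene_model_reproduces_mean_image_score(self, toy_image_model):
        # a gene model that returns the "mean" pooled statistic must agree
        # with the mean_image_score strategy exactly
        gm = GeneModel(coef=np.array([1.0, 0.0, 0.0, 0.0, 0.0]), intercept=0.0)
        rng = np.random.default_rng(3)
        F = rng.normal(0, 2, (5, 2))
        via_two_level = predict_gene(Strategy.TWO_LEVEL, toy_image_model, gm, F, "g")
        via_mean = predict_gene(Strategy.MEAN_IMAGE_SCORE, toy_image_model, None, F, "g")
        assert via_two_level.score == pytest.approx(via_mean.score, abs=1e-12)

    def test_single_image_returns_per_image_predictions(self, toy_image_model):
        F = np.array([[2.0, 2.0], [-2.0, -2.0]])
        preds = predict_gene(Strategy.SINGLE_IMAGE, toy_image_model, None, F, "g")
        assert len(preds) == 2
        assert preds[0].score > 0 > preds[1].score

    def test_image_scores_vary_across_jittered_images(self, toy_image_model):
        from ishlayer import FeaturizedDataset, LayerClass, generate_gene_images, random_spec

        spec = random_spec("g", LayerClass.GRANULAR, np.random.default_rng(5))
        ds = FeaturizedDataset.from_images(
            {"g": (LayerClass.GRANULAR, generate_gene_images(spec))}, factors=(4,)
        )
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, ds.features.shape[1]))
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        model = train_image_classifier(X, y, ImageModelConfig(cost=1.0, kernel_width=0.01))
        scores = model.scores(ds.features)
        assert np.var(scores) > 0


class TestRankGenome:
    def test_sorted_by_descending_score_then_gene_id(self, toy_image_model):
        genes = {
            "g_hi": np.array([[2.0, 2.0]]),
            "g_lo": np.array([[-2.0, -2.0]]),
            "g_empty": np.zeros((0, 2)),
        }
        ranks = rank_genome(toy_image_model, None, genes, Strategy.MEAN_IMAGE_SCORE)
        assert [p.gene_id for p in ranks] == ["g_hi", "g_lo"]
        again = rank_genome(toy_image_model, None, genes, Strategy.MEAN_IMAGE_SCORE)
        assert [(p.gene_id, p.score) for p in ranks] == [
            (p.gene_id, p.score) for p in again
        ]

    def test_single_image_strategy_rejected(self, toy_image_model):
        with pytest.raises(ValueError, match="image-level baseline"):
            rank_genome(toy_image_model, None, {}, Strategy.SINGLE_IMAGE)

    def test_planted_positives_rank_on_top(self, toy_image_model):
        rng = np.random.default_rng(9)
        genes = {f"pos{i}": rng.normal(2, 0.3, (3, 2)) for i in range(5)}
        genes |= {f"neg{i}": rng.normal(-2, 0.3, (3, 2)) for i in range(15)}
        gm = GeneModel(coef=np.array([1.0, 0, 0, 0, 0]), intercept=0.0)
        ranks = rank_genome(toy_image_model, gm, genes, Strategy.TWO_LEVEL)
        assert {p.gene_id[:3] for p in ranks[:5]} == {"pos"}
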