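"""Compare the four pooling strategies with nested cross-validation.

Evaluates one layer detector (granular vs negatives) under the two-level
classifier, mean image score, mean LBP features, and the single-image
baseline, using gene-grouped nested CV so no gene ever has images in both
train and test. Prints mean AUC +/- the standard deviation across folds;
1.0 is a perfect ranking of held-out genes, 0.5 is chance.
"""

from ishlayer import EvalConfig, FeaturizedDataset, LayerClass, evaluate_layer, generate_dataset

manifest = generate_dataset(10, 30, seed=2, out_dir="scratch/example_strategies")
ds = FeaturizedDataset.from_manifest(manifest, factors=(1, 4, 16))

results = evaluate_layer(
    ds,
    LayerClass.GRANULAR,
    ["two_level", "mean_image_score", "mean_lbp_features", "single_image"],
    EvalConfig(seed=0),
)
print("granular vs negative set (5-fold gene-grouped nested CV):")
for strategy, res in results.items():
    print(f"  {strategy.value:>18s}: AUC = {res.mean_auc:.3f} +/- {res.auc_std:.3f}")
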