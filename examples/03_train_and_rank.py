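"""Train the two-level classifier and rank unseen genes.

Trains the image-level RBF SVM and the gene-level linear SVM on one half
of a small synthetic dataset (Purkinje vs negatives), then ranks the
held-out genes by their two-level confidence score. Positive scores mean
"predicted in the target layer"; with a well-trained detector the held-out
Purkinje genes should occupy the top ranks.
"""

import numpy as np

from ishlayer import (
    FeaturizedDataset,
    ImageModelConfig,
    LayerClass,
    Strategy,
    generate_dataset,
    grid_search_hyperparams,
    pool_scores,
    rank_genome,
    train_gene_classifier,
    train_image_classifier,
)

manifest = generate_dataset(8, 16, seed=4, out_dir="scratch/example_rank")
ds = FeaturizedDataset.from_manifest(manifest, factors=(1, 4, 16))
task = ds.binary_task(LayerClass.PURKINJE)

# split genes in half (train / held-out), keeping all images of a gene together
rng = np.random.default_rng(0)
order = rng.permutation(len(task.genes))
train_g = set(task.genes[order[: len(order) // 2]])
tr = np.asarray([g in train_g for g in task.image_gene])

cfg = ImageModelConfig(grid_C=(0.5, 2.0, 8.0), grid_gamma=(2.0**-9, 2.0**-5), n_folds=3)
C, gamma = grid_search_hyperparams(task.X[tr], task.y_image[tr], task.image_gene[tr], cfg)
print(f"grid search selected C={C}, gamma={gamma}")

image_model = train_image_classifier(
    task.X[tr],
    task.y_image[tr],
    ImageModelConfig(cost=C, kernel_width=gamma),
)

# pool training-image scores per gene and fit the gene-level linear SVM
train_genes = [g for g in task.genes if g in train_g]
pools = [
    pool_scores(image_model.scores(task.X[tr][task.image_gene[tr] == g]), g)
    for g in train_genes
]
gene_model = train_gene_classifier(pools, [task.gene_labels[g] for g in train_genes])

held_out = {
    g: task.X[task.image_gene == g] for g in task.genes if g not in train_g
}
ranking = rank_genome(image_model, gene_model, held_out, Strategy.TWO_LEVEL)

print("held-out genes by two-level confidence (truth in brackets):")
for p in ranking:
    truth = "purkinje" if task.gene_labels[p.gene_id] else "negative"
    print(f"  {p.score:+8.3f}  {p.gene_id:<16s} [{truth}]")
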