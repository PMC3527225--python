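"""Featurize one expression image with multi-scale local binary patterns.

Builds the downsampling pyramid, computes the 256-bin LBP(8,2) histogram
plus mean intensity at every level (257 features per level), and prints
the layout of the concatenated feature vector.
"""

import numpy as np

from ishlayer import LayerClass, build_pyramid, generate_gene_images, image_features, random_spec

spec = random_spec("Calb1-like", LayerClass.PURKINJE, np.random.default_rng(3))
image = generate_gene_images(spec)[0]

factors = (1, 2, 4, 8, 10, 16)
pyramid = build_pyramid(image, factors)
fv = image_features(pyramid)

print(f"image {image.image_id}: {image.shape[0]}x{image.shape[1]}")
print(f"pyramid factors: {fv.level_factors}")
print(f"feature vector length: {len(fv)} (= {len(factors)} levels x 257)")
for f in factors:
    block = fv.block(f)
    top_code = int(np.argmax(block[:256]))
    print(
        f"  factor {f:>2d}: most frequent LBP code {top_code:>3d} "
        f"(scaled to {block[top_code]:.0f}), mean intensity {block[256]:.4f}"
    )
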