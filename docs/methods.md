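# Methods

This note records the model, the choices that were genuinely open, and the
limits of what the synthetic experiments show.

## Problem setting

A gene is observed through a small bag of ISH section images (typically
2–8), taken from different slices and different animals. The label — which
cerebellar layer the gene's expression is localized to — attaches to the
gene, not to any single image: a multiple-instance problem. Four layer
classes are modeled (Purkinje, granular, molecular, white matter) plus a
negative class of non-localized genes. The *molecular* class deliberately
includes expression in the Purkinje stripe as well as the outer band,
because molecular-layer genes mark Purkinje dendritic arbors whose cell
bodies sit in the Purkinje layer; the two patterns co-occur in real data.

## Image representation

* **Intensity.** RGB heat-colormapped images are inverted by
  nearest-neighbor lookup against a 256-entry table of the heat path
  (black → red → yellow → white); grayscale images map through /255. Pure
  black is exactly 0; images that are entirely zero are excluded before
  featurization (`is_blank`, exact-zero test by default with an epsilon
  exposed for lossy formats).
* **Pyramid.** Block-mean downsampling at factors {1, 2, 4, 8, 10, 16}
  (defaults; any ascending set is accepted). Partial edge blocks are
  dropped rather than padded, to avoid edge bias in texture statistics.
* **LBP(8, 2).** At each scale, every interior pixel (border of
  ceil(radius) = 2 px excluded) is encoded by comparing it with 8 samples
  on a circle of radius 2: bit b is 1 iff the bilinearly interpolated
  neighbor at angle 2πb/8 (east first, counter-clockwise) is ≥ the center.
  The ≥ tie convention makes a constant image code to 255; the bit order is
  an arbitrary fixed convention (any other fixed choice permutes histogram
  bins without changing the representation). Background zeros participate
  in codes — foreground/background boundaries are informative structure.
  The full 256-bin histogram is kept; the "uniform" bin-merging variant is
  not offered, as it discards discriminative patterns in expression images
  whose statistics differ from natural photographs.
* **Feature vector.** Per scale: histogram divided by its maximal bin
  (maximum exactly 1), then the level's raw mean intensity (already in
  [0, 1], deliberately not rescaled with the histogram block). Blocks are
  concatenated in pyramid order: 257 features per scale.
* **Invariance.** With interpolated sampling, LBP codes are exactly
  invariant under increasing *affine* intensity maps (gain/offset — the
  physically relevant staining variation); the four axis-aligned samples
  are additionally invariant under any strictly increasing map. Exact
  invariance under arbitrary monotone maps holds only for non-interpolated
  LBP variants, because interpolation does not commute with nonlinear
  transforms. Tests assert exactly these two properties.

## Classifiers

* **Image level.** RBF-kernel SVM per target layer. Class costs default to
  inverse class frequency, c+ : c− = n− : n+, so the many-negatives
  imbalance does not bias the margin. Hyper-parameters are selected by
  grid search maximizing gene-grouped cross-validated AUC over log-spaced
  grids (C ∈ 2^{−3..7}, γ ∈ 2^{−9..1}, step 2²), ties broken toward
  smaller C, then smaller γ. Internally the grid search precomputes the
  pairwise squared-distance matrix once per fold and exponentiates per γ —
  mathematically identical to direct RBF fits, but each grid point costs
  only a kernel solve.
* **Gene level.** The five pooled statistics (mean, median, top-1/2/3;
  genes with < 3 images duplicate their lowest score into the top-k slots,
  while mean and median use the original scores) feed a linear SVM whose C
  is tuned by stratified 5-fold CV. The pooled features are standardized
  internally and the scaling folded back into the returned coefficients,
  so the model is a plain linear function of raw pools whose
  regularization is invariant to the dynamic range of image scores. This
  matters: when the image classifier separates with a wide margin, pooled
  decision values can be nearly constant, and an unscaled linear SVM
  degenerates toward a zero weight vector.
* **Score centering in the nested evaluation.** The gene classifier is
  trained on out-of-fold image scores (each training image scored by an
  inner-fold model that never saw its gene) so its inputs have the same
  distribution as at test time. Decision values from different SVM fits
  share no common offset — the bias term varies between fits and can
  dominate when fits are wide-margin — so scores are centered per scoring
  model (each inner fold's validation scores around their mean; the outer
  test scores around theirs) before pooling. Centering subtracts one
  constant per model and leaves within-model rankings untouched. Without
  it, pooled out-of-fold scores with per-fold AUC 1.0 can show pooled AUC
  ≈ 0.8 purely from offset scatter.

## Evaluation protocol

Outer 5-fold cross-validation, folds assigned at the gene level,
label-stratified (per-fold class counts within one gene of even), with a
fold pointer shared across labels so overall fold sizes differ by at most
one gene. Inner 5-fold CV — drawn only from each outer training set —
tunes hyper-parameters. Every split taken is recorded as a `SplitRecord`,
and `audit_no_leakage` re-verifies after the fact that no gene sat on both
sides of any split and no outer-test gene entered inner training. AUC is
the exact Mann–Whitney statistic (average ranks, half credit for ties);
fold-wise AUCs give mean ± sample standard deviation (n−1), and ROC curves
pool the out-of-fold gene scores across folds. The negative gene set is
shared by all four one-vs-negative tasks. Pairwise (one-vs-one) confusion
is reported as 1 − mean AUC, upper-triangular.

## Synthetic data generator

The generator renders what the classifier must be robust to, not anatomy:

* **Coarse geometry.** A star-shaped section whose boundary radius is
  sinusoidally modulated with 2–4 "fingers" (amplitude 0.10–0.22, random
  phase, aspect 0.8–1.0). Layers are radial bands of the normalized radius
  u: white-matter core (u < 0.45), granule band (0.45–0.76), Purkinje
  stripe (width 0.05 above 0.76), molecular band above — each gene
  perturbs the boundaries by up to ±0.05 (layer proportions vary between
  individuals).
* **Textures.** Purkinje: smooth bright stripe. Granular: dense fine
  speckle (density 0.45–0.60, grain 1.0–1.6 px). Molecular: speckled band
  whose texture distribution deliberately overlaps the granular one
  (density 0.35–0.55), plus the co-expressed stripe. White matter: coarse
  smooth field (grain 4–7 px). Negatives cycle three sub-patterns —
  structured diffuse staining, random blobs, near-blank — emulating a
  random gene set.
* **Variability.** Per-gene staining level U(0.25, 1); per-image affine
  jitter (translation ±0.08, scale ±8%, rotation ±12°, intensity ±20%)
  with independent texture resampling; cross-layer bleed-through
  (molecular genes show up to 45% relative granule-band signal, granular
  genes up to 20% in the outer band); patchy stain dropout attenuating
  expression by up to 70% per image; sparse nonspecific background
  speckle. Background outside the section mask is exactly 0, and pixel
  values are quantized to 8 bits so in-memory images equal their PNG round
  trip byte-for-byte.
* **Defaults as study conditions.** The benchmark uses 40 genes per layer
  class, 120 negatives, 2–8 images per gene (≈ 1370 images at 256×256),
  all reproducible from one seed. Jitter amplitudes are free parameters of
  the config; the defaults above were fixed once as a plausibly harsh
  rendering of inter-individual variability.

**What the generator does not emulate:** real tissue boundaries, staining
chemistry, sectioning artifacts (tears, folds, partial sections),
non-cerebellar structures in the field of view, or the long-tailed
heterogeneity of a genuinely random negative gene set. Consequently the
synthetic benchmark is *easier* than atlas data: at the default
conditions every layer detector saturates near AUC 1.0, strategy
differences are within noise, and the granular/molecular pairwise
confusion is ≈ 0 rather than the several percent seen on real imagery.
Passing these tests demonstrates that the pipeline is implemented
correctly end to end — featurization, grouped nested CV, pooling, ranking
— not that it would reach any particular accuracy on real data.

## Numerical choices and degenerate inputs

* Median of an even score count = mean of the two central values.
* Grid-search ties (common on separable data) resolve deterministically
  toward stronger regularization (smaller C), then smaller γ.
* Squared distances are clipped at 0 before exponentiation; kernel solves
  use libsvm's default tolerance (duplicate-sample vs doubled-cost
  equivalence holds to ≈ 1e-3 in decision values).
* A histogram level that would be all-zero cannot occur (blank images are
  excluded before featurization); undersized pyramid levels raise with the
  offending factor named.
* Genes whose images are all blank are dropped at featurization;
  `rank_genome` excludes genes with no scorable images and breaks score
  ties by gene id, making rankings fully deterministic.
* All fold assignments, generator draws and derived seeds flow from
  explicit integer seeds; scoring is deterministic given a model.

## Problem sizes

Unit tests run on images from 16² to 256² and toy datasets of ≤ 24 genes;
the end-to-end benchmark (tests and `scripts/acceptance.py`) uses the full
280-gene / ≈ 1370-image synthetic study at all six scales, chosen so a
complete run finishes in a few minutes on a single CPU while keeping every
stage of the published-style protocol intact.
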