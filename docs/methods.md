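# Methods

## Problem and model

`hierpath` classifies whole-slide histopathology images (WSIs) of
duodenal biopsies into a two-level taxonomy: a parent level
{histologically Normal, Environmental Enteropathy (EE), Celiac Disease
(CD)} and, below CD, a modified-Marsh severity level {I, IIIa, IIIb,
IIIc}. WSIs are far too large to classify directly, so the pipeline is
patch-based:

1. **Tiling.** Each slide is cut into non-overlapping square patches on
   a row-major grid (default stride = patch size); partial edge windows
   are dropped, so the tile count is
   `floor((H−p)/s+1) · floor((W−p)/s+1)`. Every patch inherits its
   slide's labels.
2. **Informative-patch filter.** A convolutional autoencoder (one
   same-padded conv layer of n filters with a `2k+1` kernel, max-pool
   downsampling, dense bottleneck, mirrored decoder; the padding is
   chosen so `dim(I) = dim(decode(encode(I)))`) is trained to
   reconstruct patches; k-means with k = 2 clusters the bottleneck
   vectors; the cluster whose member patches have the higher mean pixel
   standard deviation is kept (background is near-uniform, tissue is
   textured; ties go to the lower cluster index).
3. **Stain preprocessing.** Parent-level inputs are color balanced with
   the per-pixel transform `RGB_out = (α · A · I_w · RGB_in)^γ` on
   [0, 1] intensities (α exposure gain, A a 3×3 color matrix, I_w
   diagonal illuminant gains, γ gamma); child-level inputs are stain
   normalized: optical densities `OD = −log((I+ε)/I₀)` are factorized
   as `OD ≈ W·C` with a two-column non-negative stain matrix W
   (hematoxylin, eosin) and non-negative concentration maps C, and the
   image is re-rendered through a target stain matrix with C rescaled
   so each stain's 99th percentile matches the target's. The spatial
   concentration maps are untouched, preserving tissue structure.
4. **Hierarchical CNNs.** The patch classifier is conv(32, 3×3) →
   maxpool(5) → conv(32, 3×3) → maxpool(5) → conv(64, 3×3) → maxpool(8)
   → dense(128) → softmax, ReLU activations, dropout in every block,
   same-padded convolutions so pooling alone sets the spatial
   reduction (1000 → 200 → 40 → 5 at full scale). The parent model has
   3 output nodes; the CD child model is identical but with 4 output
   nodes and is trained only on CD patches. Training is Adam
   (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−8) on sparse categorical
   cross-entropy.
5. **Whole-slide inference.** Each retained patch yields
   `p(y_ij = c | x_ij, D)`; the patch MAP label is the argmax, and the
   slide label is the argmax of the component-wise sum of its patch
   vectors (ties toward the lowest class index). If the slide's parent
   label has a child model, the same retained patches are pushed
   through it and aggregated the same way. Child aggregation uses all
   retained patches of the slide, not only those whose individual
   parent MAP was CD — the summation is defined over all patches of
   the slide and no per-patch gating is specified.
6. **Evaluation.** One-vs-rest confusion counts per class; accuracy =
   correct/total; micro precision `ΣTP/Σ(TP+FP)`, micro recall
   `ΣTP/Σ(TP+FN)`, micro F1 `Σ2TP/Σ(2TP+FP+FN)`; per-class versions
   use each class's counts alone, zero denominators are reported as
   undefined rather than 0. ± half-widths are central 95% bootstrap
   intervals over resampled test items (1000 resamples by default);
   the resampling choice is this package's own and is labeled as such.
   Grad-CAM heatmaps are the rectified, gradient-weighted sum of the
   last conv layer's feature maps, max-normalized and upsampled to the
   patch.

## Numerical core

No deep-learning framework is used: the networks are implemented in
numpy (`hierpath.nn`) with im2col convolutions, explicit backprop and a
hand-written Adam. This keeps every equation of the model inspectable
and exactly testable — Adam is checked against an independent scalar
implementation to 1e−10, and layer gradients against central finite
differences. The trade-off is CPU-scale training only, which fits the
package's synthetic working scale. k-means delegates initialization and
restarts (k-means++, 10 restarts, tol 1e−4) to scikit-learn, then
polishes with exact Lloyd steps so the returned state satisfies the
textbook invariants exactly (centroids are member means, assignments
are nearest-centroid, objective is recomputable); the test oracle is an
independent exhaustive-partition search. For tiny two-cluster inputs
(n ≤ 12) Lloyd is additionally restarted from every bipartition's
centroids — the optimal partition is a Lloyd fixed point, so the
returned solution is provably optimal there; k-means++ restarts alone
miss it on a small percentage of random instances. The stain NMF is
scikit-learn's multiplicative-update solver on background-excluded OD
pixels (mean OD < 0.15 excluded, ≤ 20k pixels subsampled, seeded),
warm-started at the canonical H&E absorption directions — without a
prior, a two-stain factorization of dense mixtures is not identifiable
(any non-negative rotation fits equally well). Tests verify the fit
genuinely adapts by recovering stain matrices rotated 10° away from
that initialization. Hematoxylin is identified as the column with the
larger blue-channel OD; I₀ = 255 and ε = 1 for 8-bit images.

## Synthetic data: what it emulates

The study's biopsy images are private, so a seeded generator stands in.
A slide is a contiguous tissue band covering `1 − background_fraction`
of the image (background: near-white with σ ≈ 2 Gaussian noise), filled
with two stain concentration fields rendered through Beer–Lambert
optics: eosin-stained elliptical blobs ("villi") plus a smooth base,
and strong hematoxylin dots of ~3 px radius ("nuclei"). Class structure:

| class  | blobs /100² | dots /100² | elongation | eosin | hema |
|--------|------------|-----------|------------|-------|------|
| Normal | 2          | 4         | 3.0        | 0.45  | 0.04 |
| EE     | 14         | 30        | 1.5        | 0.12  | 0.65 |
| CD-I   | 6          | 10        | 4.0        | 0.35  | 0.24 |
| CD-IIIa| 6          | 16        | 2.8        | 0.35  | 0.22 |
| CD-IIIb| 6          | 28        | 1.9        | 0.35  | 0.22 |
| CD-IIIc| 6          | 44        | 1.2        | 0.35  | 0.22 |

Parents differ in base stain balance and cell density (EE is
inflammation-dense and hematoxylin-shifted); severities encode
progressive villous atrophy as monotonically falling blob elongation
with rising nuclear density. A per-slide color cast of the
gain+gamma form (gains U(0.92, 1.08) per channel, gamma U(0.9, 1.1))
emulates scanner/lab variation and is exactly the forward model the
color-balancing transform can invert when the parameters are known.
A one-number statistic (red-OD share of red+green OD over tissue
pixels, gamma-invariant after white balancing) separates the parent
classes at ≥ 95% patch accuracy — certified by a property test — so
end-to-end results measure the pipeline, not an unlearnable task.
What the generator does **not** emulate: real villous/crypt geometry,
nucleus morphology, focus/compression artifacts, magnification
differences between scanners, and annotation noise. Passing end-to-end
tests therefore demonstrates that the machinery is correct and can
recover a planted, realistic-in-kind signal; it does not predict
clinical performance.

## Working scale and training recipe

The published architecture ingests 1000-pixel patches; that geometry is
built and shape-verified but not trained here. The package's working
scale, used by tests, examples and the acceptance script, is: 600-pixel
slides, 200-pixel patches, model input downscaled to 100 pixels with
pooling cascade (5, 5, 2) (sides 20, 4, 2), 8 slides per leaf class
split 6 train / 2 test. These sizes were chosen as the smallest at
which every stage has enough data to behave qualitatively like the
full-scale system. The last pool is 2, not a larger value, so the
dense head receives a 2×2 terminal feature map: collapsing to 1×1
through a final max-pool discards the spatial averages that a density
signal needs, and measurably destabilizes the severity model.

On such small slide counts two failure modes dominate and shaped the
default training configuration (`WORKING_PARENT_CONFIG` /
`WORKING_CHILD_CONFIG`): networks memorize slide-specific stain
residue instead of class structure, and end-of-training stochasticity
swamps the signal. Countermeasures, all standard: random 90°
rotations/flips during training; learning-rate decay (×1/3 at 60%,
×1/10 at 85% of epochs); tail weight-averaging over the last 15% of
epochs; no validation holdout at this scale (every patch trains); 40
epochs for the parent task and 80 for the harder severity task at
lr 0.003. Dropout is reduced to 0.1 (conv) / 0.25 (dense) at the
working scale — the full-scale defaults of 0.25/0.5 suppress learning
entirely on ~200 training patches. The full-scale defaults (epochs 20,
batch 16, lr 0.001, dropout 0.25/0.5, 90/10 validation split) remain
the plain `TrainingConfig`/`CNNArchitectureSpec` defaults.

Both classifiers consume an optical-density encoding of their
preprocessed inputs (`−log I`, scaled to [0, 1]) rather than raw
intensities. Stains combine linearly in OD, so stain amount is a
linear feature of the input and a single conv + ReLU extracts
thresholded stain density — the severity signal — directly, while the
parent's stain-ratio signal becomes a ratio of linear features;
feeding intensities forces the network to approximate the logarithm
first and costs several points of accuracy at this scale (the parent
model reaches 100% patch accuracy with OD inputs on held-out
synthetic slides, versus ~96% on intensities). A random per-patch
gamma jitter was evaluated as an additional augmentation and
rejected: with stain normalization already removing amplitude
confounds it only adds noise.

The illuminant gains for parent-level color balancing are estimated
per slide from the 99th-percentile white point of the slide's patch
mosaic (background transmits the illuminant unchanged); estimating per
patch is unreliable for tissue-only patches. The child-level stain
target is fitted on the first CD training slide (by id), making the
target deterministic for a given dataset.

## Degenerate inputs and tie-breaks

Ties in patch MAP, slide argmax and cluster selection all resolve to
the lowest index. All-white images raise on stain fitting (no tissue
OD). Slides whose patches are all filtered out raise at inference.
Empty k-means clusters keep their previous centroid during Lloyd
polishing. Pixel intensities are scaled to [0, 1] before any network.

## Known limitations

- CPU-scale numerics: training the 1000-pixel architecture is out of
  reach; it is constructed and shape-checked only.
- The severity (child) task sits near the architecture's practical
  ceiling on the working scale: its signal is a small-object density,
  which the all-max-pooling cascade is poorly matched to, and
  patch-level severity accuracy is the pipeline's weakest number
  (~0.9 at the working scale, versus 1.0 slide-level parent accuracy).
- The magnification mismatch between 20× and 40× source scanners in
  the real study is not modeled or harmonized.
- Bootstrap half-widths quantify test-set resampling uncertainty only,
  not run-to-run training variance.
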