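# Methods

## Problem and approach

Counting spikelets on a wheat spike is a standard productivity trait,
and the cheapest way to annotate training images for it is a single
expert click per spikelet center. This package implements a complete
point-supervised counting pipeline around that idea:

1. **Targets from points.** Each image's clicked centers are turned
   into one of three training targets: a binary mask of fixed-radius
   discs (default radius 2 mm), a density map summing one isotropic
   2-D Gaussian kernel per center, or fixed-size square boxes
   (default 6 × 6 mm) exportable in YOLO text format for an external
   detector. All physical sizes are converted to pixels through a
   per-dataset (or per-image) `px_per_mm` calibration.
2. **Segmentation.** An encoder–decoder network predicts, per pixel,
   either the disc mask (sigmoid output, binary cross-entropy loss)
   or the density (log-softmax over the flattened raster, forming a
   probability distribution over pixels, trained with the
   Kullback–Leibler divergence against the normalized target).
3. **Decoding.** Predicted maps are converted back to center points:
   for masks, the centroid of every thresholded 8-connected region;
   for densities, the threshold-C rule — within each candidate area,
   keep pixels whose value is at least C times the area's maximum,
   then report each surviving region's argmax pixel.
4. **Evaluation.** A predicted center is a true positive if it can be
   paired one-to-one with a true center within 2 mm; precision,
   recall and F1 summarize localization (pooled TP/FP/FN across
   images — micro-averaging — is the headline; per-image macro means
   are reported alongside), and MAE/MAPE of per-image counts
   summarize counting.

## Model

The segmentation backend is a compact U-Net-style convolutional
encoder–decoder implemented directly on numpy with explicit forward
and backward passes and an Adam optimizer: two 3×3-conv pairs with
2×2 max-pooling between levels, a conv-pair bottleneck, and a decoder
with nearest-neighbour upsampling, skip concatenation and one conv
per level, ending in a single-logit 3×3 head. Named encoder presets
set the channel widths (`unet-micro` 4/8/16 up to `unet-base`
16/32/64); the full-scale encoder names used as per-scheme defaults
(`mit_b2`, `efficientnet-b4`) alias to the largest preset. Weights
use He initialization; a `pretrained` flag is accepted but no
pretrained weights ship with these presets (a warning is emitted and
training starts from random initialization). Analytic gradients are
verified against finite differences in the test-suite.

Images are resized to a fixed training geometry — default 512 × 224
(height × width) — and predictions are bilinearly resampled back to
the original geometry before decoding, so all extracted centers and
all evaluation live in original pixel coordinates, where the
millimetre calibration is meaningful. Both resize dimensions must be
multiples of 4 (two pooling levels).

## Training recipe

Defaults follow the full-scale recipe: 500 epochs, Adam, a random
60/20/20 train/validation/test split, and an augmentation list of
horizontal flip p=0.5, vertical flip p=0.277, rotation within ±30°
p=0.735, Gaussian blur p=0.25, Gaussian noise p=0.15,
brightness/contrast p=0.5, ±15 RGB channel shift p=0.5, color jitter
(brightness/contrast/saturation/hue 0.2) p=0.703 and grayscale p=0.1.
Geometric transforms are applied identically to the image, the target
raster (nearest-neighbour for binary targets; bilinear with total
renormalization for densities) and the point coordinates; photometric
transforms touch the image only. Learning rate (1e-3), batch size
(4) and Adam betas (0.9, 0.999) are conventional defaults exposed as
configuration. Checkpoint selection uses the best validation
micro-F1 at the 2 mm radius — the same quantity the hyperparameter
search optimizes — not the loss; ties keep the earlier epoch.

The whole run is a pure function of the config seed on CPU: the
split, the augmentation draws, the weight initialization, the batch
order and hence the training history reproduce exactly.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `disc_radius_mm` | 2.0 | radius of the binary disc target |
| `sigma_mm` | 1.0 | Gaussian kernel sd; chosen so ~95 % of kernel mass lies within the 2 mm disc radius |
| box side | 6.0 mm | square box target side |
| `binary_threshold` | 0.5 | binarization level of the probability map |
| `min_region_area_px` | 0 | discard smaller regions before centroiding |
| `gaussian_C` | 0.5 | per-area relative cut of the threshold-C rule |
| `gaussian_floor` | 1e-4 | candidate-area floor, as a fraction of the global maximum |
| match radius | 2.0 mm | TP pairing radius of the evaluation |

Gaussian kernels are evaluated within ±4σ (truncated mass < 1e-4).
A disc too small to cover any pixel center still marks the point's
nearest pixel, with a warning, so annotations never silently vanish
from a target. A normalized density requested for an image without
points returns a uniform map (with a warning) so background-only
images can participate in training. MAPE excludes images with a zero
true count (division by t_i), with a warning; precision is defined as
1 when there are neither predictions nor truths and 0 when there are
truths but no predictions (symmetrically for recall), and F1 is 0
when P + R = 0.

## Matching

The 2 mm true-positive rule does not by itself say how competing
candidates are resolved. We use a maximum-cardinality one-to-one
matching on the within-radius graph, breaking ties by minimum total
distance, solved exactly with the Hungarian algorithm: out-of-radius
pairs carry a cost larger than any achievable total feasible
distance, so the solver first maximizes the number of within-radius
pairs and then minimizes their summed distance. This is
order-independent and verified against exhaustive enumeration over
all one-to-one assignments in the test-suite. A greedy nearest-pair
mode is available for comparison.

## Synthetic data

Real spike photographs for this task are not publicly available, so
the package ships a generator that emulates their geometry: textured
ellipses (default 6 × 3 mm) attached in two alternating ranks
(lateral offset 2.5 mm) at 4 mm steps along a curved rachis, on a
noisy blue background, with per-blob hue variation. The returned
annotations are the exact rendered centers; a separate jitter model
displaces each point by an isotropic Gaussian (per-axis sd
`sigma_mm`), emulating imprecise expert clicks. Per-image spikelet
counts default to the 8–21 range. The generator is deliberately not
photorealistic — no awns, glumes, overlapping spikelets, clothespins,
shadows or color-calibration cards — so passing tests demonstrate
that the pipeline's machinery is correct and trainable, not that the
model generalizes to field or laboratory photographs.

## Scaled study conditions

The end-to-end experiments run at desk scale on one CPU: 150
synthetic images of 128 × 64 px at 2 px/mm with 6–12 spikelets each,
a 60/20/20 split, the `unet-tiny` preset, 15 epochs, batch 4,
learning rate 2e-3, and no stochastic augmentation (the synthetic
generator already varies pose, curvature and color across images).
After training, the decoding parameters are selected on the
validation split from a small grid (binary: threshold
{0.3, 0.5, 0.7}; density: C {0.3, 0.5, 0.7} × floor
{1e-4, 0.05, 0.1, 0.2}) by validation micro-F1 before scoring the
held-out test split — the same validation-driven hyperparameter
selection the full-scale method uses. The floor matters for density
decoding: a normalized density over k spikelets puts each true bump
near 1/k of the mass, while background ripple sits orders of
magnitude lower but above the very permissive 1e-4 default, so a
floor of a few percent of the global maximum removes spurious peaks.

The planted-optimum tuning study searches the disc radius on a coarse
grid {0.25, 1.5, 6} mm over 10 random-search trials with a
micro-budget (40 images of 96 × 48 px, 12 epochs). The 1.5 mm radius
— the blob's minor semi-axis — is the geometrically workable choice:
0.25 mm discs cover about one pixel at 2 px/mm (far too sparse a
target for the budget) and 6 mm discs merge along the rachis into
regions whose centroids land far from every true center. Every trial
trains from the same seed so trials differ only in the radius
(a controlled comparison); repeated draws of one grid value are
therefore cached.

## Limitations

* The numpy backend is CPU-only and sized for desk-scale experiments;
  it is not a drop-in for full-resolution (512 × 224) transformer or
  EfficientNet encoders, which the presets only alias in width.
* No pretrained initialization is available for the shipped presets.
* The density decoder has no watershed splitting: two bumps closer
  than the floor/C geometry allows merge into one center.
* Box-label support covers target generation, YOLO export and
  box-to-center decoding; the detector itself is external.
* Synthetic blobs never overlap and their photometry is simplistic;
  results on synthetic data bound nothing about real spikes beyond
  the correctness of the pipeline itself.
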