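# Methods

This note documents the models and procedures implemented in `dewquant`,
the parameter defaults and the reasoning behind them, what the synthetic
scenes do and do not emulate, and the numerical conventions the test
suite pins down.

## Problem setting

The quantity of interest is the dew amount on a plant surface, measured
as the total droplet-covered area in pixels of a photograph. The
pipeline decomposes the problem into background removal by color,
droplet-contour detection, contour-to-region conversion, and per-droplet
measurement. Everything operates on 8-bit RGB input, row-major (row,
col) coordinates, 0-based indices and half-open bounding boxes; polygon
annotations use (x, y) order at the file boundary only.

## Background segmentation by color

Dew refracts the ambient light at low color saturation, while the
problematic parts of a scene — colored light patches, reflections,
pigmented surfaces that are not dew-bearing — are saturated. The
analysis mask is

    mask = erode( close( S < α ) )

with S the HSV saturation on the 0–255 scale.

* **α = 50** (saturation threshold). Pixels at or above it are excluded.
  The threshold is monotone: increasing α never removes a retained
  pixel.
* **Closing, then erosion, both with a square 25 × 25 structuring
  element.** The closing bridges small gaps in the retained region; the
  erosion shrinks the region by 12 px on every side and away from every
  exclusion, so the mask boundary cannot later be mistaken for a droplet
  contour. Structuring-element sides must be odd (even sides have no
  center pixel).
* **Border convention.** Dilation and erosion both treat the plane
  outside the frame as background. Closing is computed on the
  zero-padded plane (the dilation may overflow the frame before the
  erosion pulls it back), which keeps closing extensive and idempotent
  including at the border; a full-frame mask therefore loses a 12-px
  border band to the final erosion, and scenes whose droplets must
  survive segmentation intact should keep them at least that far from
  the frame edge (`SceneConfig.border_margin_px`).
* **Excluded pixels** are filled with 0 (black) in the masked image;
  the fill value is configurable, and the mask itself travels
  downstream so detectors can suppress mask-boundary artefacts.

A consequence of α = 50 worth stating: the dew-bearing surface itself
must photograph below the threshold, or the erosion will consume the
droplets along with the background. Leaves under diffuse light do
(waxy cuticle, desaturated green); strongly lit pigment or colored
glare does not, which is exactly what the stage is meant to remove.

## Edge detection

### Classical baselines

* **Canny** — Gaussian smoothing (σ = 1.0), gradient magnitude,
  non-maximum suppression, hysteresis with (low, high) = (64, 81) on the
  8-bit scale. Deterministic, thin (1-px) contours; no notion of
  contour closure.
* **Laplacian zero-crossing** — 3 × 3 Laplacian response; a pixel is an
  edge where the response changes sign against its right or lower
  neighbour with a jump of at least 5 intensity levels (of the pixel
  pair straddling the crossing, the one with the smaller absolute
  response is marked). Invariant to adding a constant to the image.

### Multi-scale convolutional edge network

A residual backbone of K stages; stage k ≥ 2 halves the resolution with
a stride-2 convolution. Each stage is a sequence of residual blocks
(3 × 3 conv → ReLU → 3 × 3 conv, plus an identity or 1 × 1-projected
skip). *Every block* — not only each stage's last — feeds a side
branch: 1 × 1 conv to 21 channels, summed over the stage's blocks,
1 × 1 conv to one channel, bilinear upsampling to input resolution.
The K side logit maps are concatenated and projected by a 1 × 1
convolution to the fused output; all outputs pass through a sigmoid.
Tapping every convolutional block preserves the fine features that thin
droplet contours live in.

Presets: `tiny` (2 stages, 8/16 channels, 1 block each — trainable in
seconds on one CPU core), `small` (3 stages), `full` (5 stages,
16–256 channels, 2 blocks each — the structure intended for
photograph-scale work). All presets share the side-branch and fusion
topology, so conclusions drawn on the small ones transfer
architecturally.

Implementation: pure numpy with a minimal reverse-mode tape
(`dewquant.irrd.autograd`) — im2col convolution, ReLU, add, channel
concat, and bilinear upsampling expressed as two fixed interpolation
matrices (so its adjoint is exact). Gradients are verified against
central finite differences in the test suite. Single-threaded numpy
makes every result bit-reproducible for fixed seeds.

Input images are converted to gray and standardised per image (mean 0,
standard deviation 1). Raw [0, 1] gray input is all-positive with a
background-dominated mean, which conditions the first layers badly and
can stall training in a flat-output saddle; standardisation removed the
stall on every seed tried. When an analysis mask is supplied at
inference, the statistics are computed over retained pixels only and
excluded pixels are held at the mean, so the mask boundary does not
masquerade as a step edge; masked regions are then zeroed in the output.

Initialisation is He fan-in scaling for all convolution weights (ReLU
appropriate), zero biases, and 1/K constants for the fusion projection
(the fused map starts as the mean of the side maps). Two builds with
the same seed are parameter-identical.

## The contour-search loss

Ground truth is a consensus edge probability map: each of k annotators
contributes a binary contour map, and y is their per-pixel mean, so
y ∈ {0, 1/k, …, 1}. With consensus threshold η:

* y = 0 — certain non-edge, loss −α_w · log(1 − p);
* 0 < y < η — controversial, contributes exactly zero for any
  prediction (and zero gradient);
* y ≥ η — certain edge, loss −β_w · log p.

The class weights couple edge learning to the areas the contours must
enclose. With |Y⁺|, |Y⁻| the certain-edge and certain-non-edge counts,
|S⁺| the area of the largest dew region, |S⁻| the total dew area and
R = |S⁺| / (|S⁺| + |S⁻|):

    α_w = λ · |Y⁺| / (|Y⁺| + |Y⁻|) · R
    β_w =     |Y⁻| / (|Y⁺| + |Y⁻|) · R

α_w is linear in λ; β_w is independent of it. R = 1/2 exactly when the
image holds a single dew region; with no dew region at all R
degenerates (0/0) and falls back to 1/2, reducing the loss to plain
class-balanced cross-entropy. The mean area of the non-largest regions
is exposed in `AreaBalance.s_bar` for diagnostics but does not enter the
weights. The image loss is the pointwise loss summed over all pixels of
each of the K side maps plus the fused map; it is reported both as a
total and as a per-pixel mean (total / (|I| · (K + 1))).

Defaults: **η = 0.5** (a pixel is an edge if at least half the
annotators say so), **λ = 1.1** (slight extra pressure on false
positives). Predictions are clamped to [1e−7, 1 − 1e−7] before the
logarithms. The loss is non-negative and vanishes at the optimum up to
the clamp.

## Training

Plain SGD, momentum 0.9, weight decay 0, **learning rate 0.01**,
**batch size 1**, **30 epochs**; weight snapshots every 1000 steps plus
a final checkpoint (self-describing .npz with config, parameters and
metadata). Divergence (non-finite loss) aborts with a diagnostic.

The gradient of the per-image loss is normalised by (K + 1) times the
image's certain-edge pixel count. This makes the update magnitude track
the amount of contour in the image rather than the frame area: a small
desk-scale frame and a full-resolution photograph with proportional
contours receive comparable steps per contour pixel, and the quoted
learning rate remains meaningful across scales. (Normalising by the
full pixel count instead makes desk-scale steps ~25× too small and
training plateaus far above the achievable floor; the floor was
estimated with a distance-informed oracle predictor at ~0.0004 mean
loss under 1-px annotator jitter.) The loss *trace* records per-pixel
means: entry 0 is the freshly initialised network evaluated before any
update, then one mean per epoch.

## Contour post-processing

From an edge probability map to droplet regions:

1. **Binarise** at a fixed threshold or, by default, per-image Otsu
   (0.5 fallback for constant maps).
2. **Bridge and fill**: dilate by 1 px, fill holes (background
   components not connected to the frame border), erode back. Closed
   contours with gaps up to ~2 px become solid regions.
3. **Centerline shrink** (`contour_halfwidth_px = 1`): one extra
   erosion. A detected contour is at least one pixel thick and
   straddles the true boundary, so the filled region extends to the
   contour's outer extremity; without the shrink, measured areas carry a
   systematic +1-px radial bias (~20 % on a 20-px droplet).
4. **Opening** (3 × 3) to remove specks — applied to the *filled region
   mask*, not the raw edge map: a 3 × 3 opening would erase the 1-px
   contours Canny emits before they could be filled, while on solid
   regions it removes specks and hair-lines as intended.
5. **Size filter**: regions below 9 px (noise) or above 5 % of the
   image area (HSV-boundary artefacts) are removed. The 5 % default is
   calibrated to photograph-scale frames; small test frames must keep
   their largest droplet under it.
6. **Extraction**: 8-connected labelling; per-region area, centroid,
   closed outer contour and half-open bbox. Region tables are sorted by
   area descending.

Detection-to-truth correspondence is greedy on pixel overlap with
centroid-distance tie-breaks; unmatched truth droplets score a detected
area of 0.

## Evaluation metrics

* **Ap of dew area** — mean over annotated droplets of
  clamp(1 − |S_MAN − S_ALM| / S_MAN, 0, 1). The clamp makes gross
  over-detection score 0 rather than being rewarded; the unclamped form
  would exceed 1 whenever S_ALM > S_MAN.
* **Edge matching** — one-to-one, maximum-cardinality bipartite matching
  of predicted to ground-truth edge pixels within a Euclidean tolerance
  (default 0.75 % of the image diagonal), so the true-positive count is
  the largest achievable and agrees with an exhaustive matcher by
  construction.
* **Ap of edge** — area under the precision–recall curve over a grid of
  33 thresholds in (0, 1), recall-sorted trapezoid, anchored at recall 0
  with the precision of the lowest-recall point.
* **ODS / OIS** — best F-measure at a single dataset-wide threshold
  (counts pooled over images) and the mean of per-image best
  F-measures. On a one-image dataset the two coincide.
* Controversial pixels (0 < y < η) are excluded from both sides of the
  matching, mirroring their exclusion from the loss; predictions there
  neither help nor hurt.
* Precision is defined as 1 when nothing is predicted and nothing should
  be, 0 when nothing is predicted but something should be; F = 0 when
  P + R = 0.

## Synthetic scenes

The generator emulates a dew-photography bench at a default scale of
20 px/mm, so the field-relevant 1–5 mm droplets map to 20–100 px
equivalent diameters.

* **Droplets**: anti-aliased ellipses (aspect 0.85–1.18, random
  orientation), non-overlapping, fully inside the frame; a darker
  annular rim (the optical edge a detector must find), an interior that
  refracts the local background at reduced saturation and raised
  brightness, and an optional specular highlight. Labels are pixel sets
  at ≥ 0.5 coverage; a one-droplet scene with a circular droplet of
  radius r has area within 5 % of πr².
* **Backgrounds**: `leaf` (green hue 95–140°, saturation ≈ 36 ± 10 —
  deliberately below α so the dew-bearing surface stays analysable),
  `glass` (near-achromatic gray), `complex` (leaf plus at least two
  interference patches).
* **Interference patches**: rectangles/ellipses of saturated random hue
  (S ≥ 200 by default, S = 255 in the exclusion tests), recorded in
  `GroundTruth.noise_patch_mask` so exclusion is measurable.
* **Ground-truth contours** are drawn on the one-pixel *outer* boundary
  (background pixels 4-adjacent to a droplet): that is where
  gradient-based detectors localise the boundary, and it makes the
  enclosed interior exactly the labelled region, so the perfect-contour
  chain and the Canny chain measure areas under one convention.
* **Annotator model**: each of k synthetic annotators redraws the true
  contour displaced by a smooth random vector field clipped to the
  jitter radius (Euclidean, integer-snapped); the consensus is their
  mean. Defaults k = 4, jitter 1 px. This models spatially correlated
  human imprecision, not gross errors (missed droplets, hallucinated
  contours).
* **Augmentation**: crop, rotate, scale — the label map and consensus
  map undergo the same geometric transform (nearest-neighbour, so label
  ids and consensus levels survive); areas are recounted from the
  transformed label map; a transform that leaves no droplet raises.
* **Export**: per scene an RGB PNG, a 16-bit label-map PNG (supports
  more than 255 droplets), the float consensus raster as .npy with an
  8-bit PNG preview (scale recorded in the manifest), and a
  Labelme-style polygon JSON; a manifest lists files and seeds.
  Everything round-trips losslessly except the consensus preview.

What passing tests on these scenes do **not** show: robustness to
out-of-focus droplets, overlapping or coalescing droplets, translucent
droplets over high-frequency leaf venation, shadows, or annotator
mistakes beyond small displacement. Real-photograph performance must be
established on real annotated photographs.

## Determinism

Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); single-threaded numpy arithmetic makes
scene rendering, training traces and pipeline reports bit-identical
across runs with the same seeds. Scene i of a dataset uses
`config.seed + i`; derived seeds stay below 2³¹.

## Known limitations

* The deterministic Canny path assumes clean, well-separated droplets;
  touching droplets merge into one region (no watershed splitting).
* The 12-px mask erosion border means droplets within ~14 px of the
  frame edge are partially or wholly lost; at photograph scale this is
  a thin margin, at small test scale it must be budgeted for.
* The numpy network is CPU-bound and single-image; the `full` preset is
  architecturally faithful but impractical to train at photograph scale
  in this implementation.
* Otsu binarisation assumes a bimodal probability map; a fixed
  threshold is exposed for maps that are not.
* The dew-area metric is undefined for scenes with zero annotated
  droplets (it raises rather than guessing).
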