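# dewquant

Quantifying dew on plant leaves from photographs.

During drought and rehydration, dew on leaves and stems sustains
photosynthetic activity and delays wilting, so the *amount* of dew — the
total droplet-covered area — is an ecophysiological quantity worth
measuring. Doing it by computer vision is hard for two reasons: field
scenes are full of colored interference (leaf pigment, specular light,
reflections) that confuses edge detectors, and droplets of 1–5 mm
project to small, thin, easily-broken contours.

`dewquant` implements a complete measurement pipeline:

1. **Background segmentation by color.** The image is converted to HSV
   and thresholded on saturation, `I_C = I_S < α` with α = 50 on the
   8-bit scale: dew is nearly achromatic, colored interference is not.
   A morphological closing and an erosion (square structuring element,
   side 25) regularise the retained region and pull it away from its own
   boundary.
2. **Edge detection.** Either classical operators — Canny with the
   (64, 81) hysteresis pair, or Laplacian zero-crossing — or a
   multi-scale convolutional edge network: a residual backbone in which
   *every* convolutional block feeds a side branch (1×1 conv → 21
   channels, summed per stage, 1×1 conv → 1 channel, bilinear upsample);
   the K side outputs are concatenated and fused by a final 1×1
   convolution. Implemented in pure numpy with hand-written
   backpropagation — no deep-learning framework required.
3. **A contour-search loss.** Ground truth is a consensus map y ∈ [0, 1]
   (fraction of annotators marking each pixel). With η the consensus
   threshold, the per-pixel loss is

   ```
   l(X_i; W) = −α_w · log(1 − P(X_i; W))   if y_i = 0
             = 0                           if 0 < y_i < η   (controversial)
             = −β_w  · log P(X_i; W)       if y_i ≥ η
   ```

   with class weights tied to the droplet areas the contours must
   enclose: `α_w = λ · |Y⁺|/(|Y⁺|+|Y⁻|) · R`,
   `β_w = |Y⁻|/(|Y⁺|+|Y⁻|) · R`, where `R = |S⁺|/(|S⁺|+|S⁻|)` is the
   ratio of the largest dew region to the total dew area. The image
   loss sums over all K side outputs plus the fused output.
4. **Contour post-processing.** Binarisation (Otsu by default), 1-px gap
   bridging, hole filling, speck opening and a size filter turn the edge
   map into solid droplet regions with areas, centroids and contours.
5. **Evaluation.** Ap of dew area (mean per-droplet
   `1 − |S_MAN − S_ALM| / S_MAN`, clamped to [0, 1]), Ap of edge (area
   under the distance-tolerant precision–recall curve) and the ODS/OIS
   F-measures.

Because no public dew dataset exists, the package includes a synthetic
scene generator with pixel-exact ground truth (droplet label maps,
per-droplet areas, k-annotator consensus edge maps) on leaf, glass and
interference-contaminated backgrounds; every claim the test suite makes
is scored against that exact truth.

## Worked example

```python
from dewquant import SceneConfig, generate_scene, run_pipeline

config = SceneConfig(
    image_width=256, image_height=256, n_droplets=5,
    droplet_diameter_range=(20, 60), background_kind="glass",
    border_margin_px=14, seed=203,
)
image, gt = generate_scene(config)
result = run_pipeline(image, method="canny",
                      gt_label_map=gt.droplet_label_map,
                      gt_consensus=gt.consensus_edges)
print(result.report)
```

prints (`examples/03_detect_and_measure.py`):

```
droplets: detected 5, truth 5
total dew area: 6725 px
Ap of dew area: 0.957   (1.0 = every area exact)
Ap of edge:     0.435
ODS / OIS:      0.606 / 0.606
```

All five droplets are recovered and each area is within a few percent of
truth (Ap of dew area 0.957); the modest edge scores reflect Canny's
unweighted binary output. Training the edge network
(`examples/04_train_edge_network.py`: tiny preset, 16 small scenes,
lr 0.01, batch size 1, 30 epochs, under a minute on one CPU core) and
running the same comparison on a leaf-background scene gives

```
canny : detected 3/3 Ap_dew=0.931 ODS=0.614 OIS=0.614
irrd  : detected 3/3 Ap_dew=0.944 ODS=0.785 OIS=0.785
```

— the learned, area-weighted detector closes contours more reliably than
the classical baseline on the harder background.

The `examples/` directory has one short script per capability
(generation, segmentation, detection + measurement, training,
annotation round-trips). A thin CLI mirrors the pipeline stages:

```bash
dewquant --seed 5 generate scenes/ --n-scenes 4 --background leaf
dewquant detect scenes/scene_000.png --method canny --out out/
dewquant evaluate scenes/scene_000.png scenes/scene_000.json --method canny
dewquant train scenes/ --out checkpoints/
```

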