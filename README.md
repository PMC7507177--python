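# vascnet

Segmentation and architectural quantification of 2D fluorescent images of
blood-vessel networks.

Changes in microvascular architecture — angiogenesis, capillary regression,
vasodilation — are read out from confocal maximum-intensity projections of
fluorescently labeled vessels (e.g. lectin-stained murine retina). `vascnet`
turns such an image into a binary vessel segmentation, a unit-width
centerline with per-pixel radii, and four standard architecture metrics, and
can score any segmentation pixel-by-pixel against a ground-truth mask. A
synthetic phantom generator with analytic ground truth makes every stage
testable without benchmark data.

## Method

**Stage (a) — segmentation by intensity over local background.** The image
(normalized to [0, 1] by its dtype maximum) is lightly blurred (3×3 mean),
a background estimate is formed with a large k×k mean filter (default
k = 128 px) and subtracted, and the result is thresholded (default 0.045).
The initial mask is cleaned by keeping pixels with ≥4 of 8 true neighbors,
removing 8-connected components under 1600 px, smoothing the border with an
11×11 local-majority filter, filling background holes under 800 px, one
homotopic thinning pass (compensating the net one-pixel dilation of the
smoothing steps), and a final small-component removal.

**Stage (b) — centerline extraction and thickness pruning.** The mask is
consolidated (8× extensive ≥4-neighbor filter; 4× bridge+fill; majority;
holes < 80 px filled), then thinned to convergence with edge-replication
padding so centerlines reach the image border. The Euclidean distance
transform (EDT) of the segmentation, sampled on the centerline, gives the
local vessel radius r(p). The centerline is cut at branch pixels (≥3
skeleton neighbors) into segments; segments with mean radius below the
thickness threshold (default 3 px) are pruned, junctions that still join ≥2
surviving segments are restored, and the result is spur/clean/thinned once
more. Branchpoints and endpoints are reported away from the image border.

**Metrics.** For pixel size `s` (µm/px) on an H×W image:

- vessel length density = `N_centerline · s · 10⁻³ / (H·W·s²·10⁻⁶)` mm/mm²
  (raw pixel count — no diagonal correction),
- vessel area fraction = `N_segmented / (H·W)`,
- mean vessel diameter = `mean_p (2·EDT(p) − 1) · s` µm over centerline
  pixels,
- branchpoint count = number of skeleton junctions (8-connected clusters of
  branch pixels counted once).

**Evaluation.** Pixel confusion counts (TP, TN, FP, FN) against a reference
mask give accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and precision TP/(TP+FP). Metric-level error is E = Y − G with
absolute error |E|, and the per-image precision statistic |E − median(E)|
(the Brown–Forsythe transform).

## Worked example

```python
from vascnet import (PhantomSpec, generate_phantom, analyze_image,
                     confusion_counts, segmentation_scores)

spec = PhantomSpec(seed=3, noise_sigma=0.05, background_gradient_amplitude=0.10)
truth, img = generate_phantom(spec)          # random vascular tree, 512×512
res = analyze_image(img)                     # segment + skeletonize + quantify
m, e = res.metrics, truth.expected_metrics
s = segmentation_scores(confusion_counts(res.segmentation.mask, truth.truth_seg))
print(f"measured: VLD={m.vessel_length_density:.3f} mm/mm2  "
      f"AF={m.vessel_area_fraction:.4f}  D={m.mean_vessel_diameter:.2f} um  "
      f"BP={m.branchpoint_count}")
```

prints

```
measured: VLD=2.911 mm/mm2  AF=0.0250  D=6.36 um  BP=1
expected: VLD=2.966 mm/mm2  AF=0.0243  D=6.20 um  BP=1
segmentation accuracy vs truth: 0.9989  sensitivity: 0.9907  specificity: 0.9991
```

i.e. on a noisy phantom the pipeline recovers the network's length density
within ~2%, area fraction within ~3%, mean diameter within ~0.2 px, and the
single junction exactly, with >99% pixel agreement against the known
footprint.

The same pipeline is available from the shell:

```sh
vascnet phantom --preset tree --seed 3 --out-dir demo/
vascnet segment demo/image.tif --pixel-size-um 1.035 --out-mask demo/seg.png
vascnet skeleton demo/seg.png --pixel-size-um 1.035 \
    --out-centerline demo/cl.png --out-points demo/points.csv
vascnet evaluate --pred demo/seg.png --truth demo/truth_seg.png --out demo/scores.csv
vascnet run --input-dir images/ --glob "*.tif" --pixel-size-um 1.035 --out-dir out/
```

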