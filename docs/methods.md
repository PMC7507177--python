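# Methods

## Pipeline model and assumptions

The pipeline assumes a single-channel 2D image in which vessels are bright,
roughly tubular structures on a dimmer, slowly varying background — the
situation produced by maximum-intensity projection of a confocal z-stack of
fluorescently labeled vasculature. Detection is purely intensity-over-local-
background: no vesselness filters, no machine learning. This keeps every
step deterministic and auditable, at the cost of sensitivity to structures
whose contrast against the *local* background is below the threshold.

All intensities are normalized to [0, 1] by the source dtype maximum (255 or
65535), so the grey-to-binary threshold has one meaning for 8- and 16-bit
inputs. The physical pixel size is user-supplied; nothing is parsed from
image metadata.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `averaging_filter_size` | 128 | px | background (low-frequency) estimate; must exceed the widest vessel. 128 px ≈ 40 µm at the 20× reference resolution |
| `grey_to_binary_threshold` | 0.045 | intensity | applied to (light blur − background); strict `>` |
| `min_connected_component_area` | 1600 | px | vessels form large connected components; smaller blobs are debris (≈155 µm² at 20×) |
| `wire_dilation_threshold` | 0 | px | optional mask dilation before skeletonization (0 = off) |
| `vessel_thickness_threshold` | 3 | px | centerline segments with mean radius below this are pruned (0.9 µm at 20×, 0.6 µm at 60×) |
| `light_blur_size` | 3 | px | denoising mean filter over the pixel's 8-neighborhood |
| `hole_fill_area_seg` | 800 | px | background holes below this are filled in the segmentation |
| `hole_fill_area_centerline` | 80 | px | the tighter hole fill before skeletonization |
| `smooth_filter_size` | 11 | px | local-majority border smoothing window |

The light blur deserves a note: it is a 3×3 window (the pixel plus its
8-neighborhood). A substantially larger averaging window is quantitatively
inconsistent with the rest of the parameter set — with an 8×8 box, any pixel
whose window overlaps a bright tube by one column already clears the 0.045
threshold, dilating every vessel by ~4 px per side, which no single
compensating thinning pass could undo. With the 3×3 window the dilation is
one pixel, which the pipeline's one thinning pass removes exactly; on sharp
axis-aligned test tubes the final mask reproduces the drawn width to the
pixel.

Defaults are calibrated for ~1 µm/px sampling (20×–60× magnification
objectives); far outside that range the pixel-denominated parameters must be
rescaled.

## Morphological semantics

All semantics are pinned explicitly: foreground connectivity 8, background
and hole connectivity 4 (topological duals); off-image neighbors count as
background; area thresholds are strict (`< area` is removed/filled, `= area`
survives); box filters of size k anchor the output pixel at offset
⌊k/2⌋ inside the window and pad by edge replication.

Thinning is sequential homotopic thinning: per pass, the north, east, south
and west border pixels (candidate sets frozen at pass start) are visited in
row-major order, and a pixel is deleted only if it is still an (8,4)-simple
point — its true 8-neighbors form one 8-connected group and its false
neighbors one 4-connected group touching an edge-neighbor — and not a line
endpoint. Freezing candidates per pass makes one pass peel exactly one
boundary layer, so `thin(1)` is a calibrated single-pixel erosion and
`thin(inf)` converges to a unit-width, idempotent skeleton with exactly the
input's component and hole counts. The widely used parallel thinning
routines were measured to violate these guarantees on dense inputs (merged
holes, residual 2×2 blocks), which is why the primitive is implemented here
rather than delegated. One caveat is inherent to the topology: a 2×2 block
whose four corners carry diagonal arms cannot be deleted by *any* homotopic
rule; such configurations occur in adversarial salt-and-pepper masks but not
in the blob-like masks this pipeline thins.

Centerlines of vessels that cross the image border are extracted with
edge-replication padding (width adapted to the thickest structure) so the
skeleton reaches the border instead of retracting.

## Branchpoints

A branch pixel is a centerline pixel with ≥3 centerline 8-neighbors.
Thinned junctions frequently consist of 2–4 adjacent branch pixels (an
X-crossing thins to two T-configurations), so branch pixels are clustered
by 8-connectivity and each cluster is reported once, at its row-major first
pixel. Clusters touching the outermost row/column are discarded — edge
effects there produce false junctions. The same clustering governs junction
restoration after pruning: a cluster is restored iff ≥2 surviving segments
touch it (restoring single pixels can disconnect arms that meet through the
rest of the cluster).

## What the phantom generator emulates — and what it does not

`synthetic.generate_phantom` draws a network graph (single tube, Y-junction,
k×k grid, or an angle-jittered random tree with junctions ≥20 px apart and
guaranteed clearance between non-adjacent branches), rasterizes stadium
footprints (pixel centers within diameter/2 of the polyline) and a
unit-width centerline, and renders background + low-frequency gradient +
plateau, softened by a Gaussian PSF surrogate (σ = 0.2 px, the sub-pixel
lateral resolution of a 20× confocal at ~1 µm sampling) with additive
Gaussian noise. Default conditions: 512×512 px at 530/512 ≈ 1.035 µm/px,
plateau 0.75 over background 0.05, odd diameters 7–15 px (odd because
2·EDT−1 recovers odd axis-aligned widths exactly), 8 branches.

Expected values are analytic and pipeline-independent:

- area fraction: exact count of the rasterized footprint;
- length density: **chessboard** (Chebyshev) arc length of the polylines —
  the metric that a raw pixel count of an 8-connected skeleton measures,
  matching the length definition used by the pipeline (no √2 correction);
- mean diameter: the 2·EDT−1 estimator evaluated on the truth masks. The
  drawn-diameter mean is recorded separately (`drawn_mean_diameter_um`)
  because the estimator itself reads oblique tubes 0.4–1.2 px low on the
  lattice — a property of the estimator, not of any implementation, and a
  known caveat when comparing diameters across image orientations;
- branchpoint count: graph vertices of degree ≥3.

What the phantoms do **not** model: depth-dependent blur and projection
artifacts of real z-stacks, intensity falloff along vessels, labeling
heterogeneity, crossing (non-anastomosed) vessels from different depths,
photon (Poisson) noise, and tortuous curved vessels (branches are straight
segments). Passing the recovery suites therefore demonstrates correctness
of the algorithmic chain under the stated image model, not performance on
real tissue.

Known systematic effects visible in the recovery numbers: discrete thinning
retracts skeleton tips by roughly the local radius (plus one spur pixel), so
measured length density runs a few percent below the analytic value — about
3–7% for trees of ~8 branches; the published tolerance of 5% holds for the
standard suite conditions but the bias grows for trees dominated by short,
thick branches.

## Numerical and degenerate-input choices

- Threshold comparisons are strict (`>`); negative background-subtracted
  values are kept (thresholding treats them identically).
- Mean diameter of an empty centerline is NaN and is written as an empty
  CSV field — missing, never 0.
- Medians over an even number of images are the midpoint of the two central
  order statistics.
- Scores with zero denominators (e.g. precision when TP+FP = 0) are NaN.
- `segmentation_scores` reports both the standard sensitivity TP/(TP+FN)
  and precision TP/(TP+FP) so either reading of a published sensitivity
  number can be reproduced.
- Phantom generation retries bounded (300 placements × 60 restarts) and
  raises `PhantomGenerationError` for infeasible specs; all sampling is
  driven by `numpy.random.default_rng(seed)` and is bit-reproducible.

## Problem sizes used in the validation suites

The recovery suites run 10 noise-free and 10 noisy phantoms at the default
512×512 size; morphology oracles use ≥100 random masks up to 16×16 against
exhaustive brute force, and the thinning contract 100 random 32×32 blob
masks. These sizes make the full suite complete in well under a minute
while exercising every branch of the pipeline.

## Limitations

- Pixel-denominated defaults tie the pipeline to ~1 µm/px imagery.
- The ≥3-neighbor branch rule with cluster merging can still merge two true
  junctions closer than ~3 px; the generator keeps junctions ≥20 px apart,
  and real capillary junctions at 1 µm/px rarely collide at that scale.
- Length density uses raw pixel counts by definition, underestimating
  Euclidean length of oblique vessels by up to √2; comparisons are
  consistent as long as all images are analyzed with the same convention.
- `wire_dilation_threshold` defaults to 0 (off); its positive branch is a
  plain pre-skeleton dilation.
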