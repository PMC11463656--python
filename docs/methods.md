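# Methods

## Stain model

AT8 immunohistochemistry develops phosphorylated-tau signal with the
brown chromogen DAB over a hematoxylin counterstain.  We model
transmitted light with Beer–Lambert: optical density OD = −log₁₀(I/255)
per RGB channel, and stains mix additively in OD.  The stain basis is
the standard Ruifrok–Johnston H/E/DAB matrix with rows normalized to
unit length; unmixing is multiplication by its inverse.  We implement
the projection directly (rather than delegating to a library routine
that uses natural-log scaling with an offset constant) so that the
synthetic renderer and the unmixer share one matrix and the
render→unmix round trip is self-consistent: for OD fields up to ~1.2,
8-bit quantization bounds the round-trip error at ≤ 0.02 OD.

Zero pixels are clamped to 1/255 before the log.  Rendering works in
float32; quantization to uint8 is the only lossy step.

## Synthetic scenes

The generator emulates the features of AT8 temporal-cortex tiles that
the pipeline's filters exist to handle, not their photorealism:

- **Tangles** are an elliptical soma plus 1–2 tapered triangular
  protrusions along the orientation axis, with the nucleolus point
  offset slightly from the soma center.  Default soma semi-axes
  (48–68 × 32–46 px at 0.11 μm/px) and protrusion lengths (40–80 px)
  were chosen so rendered masks land near 5–6% of a 400×400 tile
  (~8–10k px), the typical scale of mature tangles at this
  magnification; the real size distribution is broader (roughly 400 to
  51,000 px) and is not matched in its tails.
- **Distractors** are smaller, rounder, weaker-stained blobs without a
  nucleolus point — objects that fail the annotation criteria but are
  DAB-positive.
- **Background** is uniform hematoxylin at OD 0.25.  **Noise** is
  per-pixel Bernoulli DAB speckle (rate = the `noise` parameter, OD
  0.35), emulating diffuse tau background; optional Gaussian sensor
  noise (σ in 8-bit units) is off by default.
- Objects are placed by rejection sampling with a minimum
  center-to-center separation (default 300 px) and an edge margin;
  exhaustion raises a capacity error rather than silently overlapping.

Scenes are bit-reproducible from (parameters, seed).  What passing
tests show: the geometric and photometric contracts of every stage hold
exactly on data whose truth is known.  What they do not show:
robustness to real-tissue phenomena the generator omits — pre-tangles
and ghost tangles, stain batch variation, tissue folds, out-of-focus
regions, and densely clustered pathology.

## Point-to-mask bootstrapping

Tiles are 400×400 px, cropped so the annotation lands on pixel index
(200, 200) (white padding at ROI borders keeps the object centered, and
white never enters the DAB mask).  The DAB channel is min-max
normalized **per tile**, Otsu-thresholded on a 256-bin histogram
(≥ threshold is foreground), then opened and closed with a disk of
radius 3 px — the smallest element that removes single-pixel speckle
without eroding the ~400 px² minimum masks; the radius is exposed.

Blob filtering labels components at 8-connectivity (configurable) and
applies two sequential rules in one labeling pass:

1. **Center bias**: drop components whose unweighted foreground
   centroid is farther than 120 px from pixel (200, 200).  Distances
   are measured from the pixel the annotation occupies, not the
   geometric tile center, so a centroid at exactly 120 px is kept.
   The default is the corrected operating point; the legacy first-pass
   value of 80 px is reproducible via configuration.
2. **Relative size**: among survivors, find the largest and drop any
   strictly smaller than half its area (a blob at exactly 50% is kept).

An empty result is valid — it flags a point on unstainable tissue — and
is surfaced by the QC report together with over-size outliers
(fraction > 0.32 of the tile), which are retained rather than
hand-edited to keep the pipeline fully automated.

Note one subtlety: retained foreground is *not* globally monotone in
the center-bias radius.  A looser radius can admit a larger blob whose
arrival makes the 50% rule evict blobs that a stricter radius kept.
The centroid stage alone is monotone, and that is the property we test.

## Tiling and balanced sampling

Training tiles are 1024 px at stride 1024; a tile is positive iff a
point annotation falls in its half-open extent, so an edge point
belongs to exactly one tile.  Clipped border tiles are kept for
inference coverage but excluded from training draws (uniform tile
shape).  The balanced sampler draws with replacement: positive with
probability 0.5, uniform within class — equivalent to weighting tiles
by inverse class frequency, so the expected positive share equals the
target regardless of imbalance.

## Metrics

Pixel scores derive from summed TP/FP/FN/TN counts (micro-averaging)
within an ROI; ROI-level reporting averages scores across ROIs.  The
probability threshold is inclusive (≥ 0.5).  Negative IOU is
tn/(tn+fp+fn); mIOU is the mean of positive and negative IOU; the
Tversky index TP/(TP + α·FN + β·FP) reduces to F1 at α = β = ½ (checked
numerically).  AUROC uses midrank tie handling (scikit-learn) and is
verified against an O(n²) pairwise oracle.  The random baseline is the
F1 of a null model with precision equal to positive-pixel prevalence
and a fixed recall of 0.5.

Object matching is greedy by descending IOU (an optimal-assignment
variant is available behind a flag).  A pair is accepted when its IOU
is positive and at least `min_iou`; the default 0.001 discards
near-zero overlaps as false positives, and `min_iou=0` accepts any
strictly positive overlap.  Box merging takes connected components of
the center-distance graph (≤ 150 px), replaces each with its enclosing
box, and iterates to a fixpoint — deterministic, order-independent and
idempotent.  Average precision uses all-point interpolation; AP@50:95
averages thresholds 0.50:0.05:0.95.

## Slide scoring

Inference slides a predictor over non-overlapping 1024-px tiles.  The
default predictor is the classical DAB-threshold pipeline; any callable
mapping a tile to a per-pixel probability map plugs in (a trained
segmentation network would occupy the same slot).  Detected masks are
reduced 64× by block-max — chosen over mean or subsampling so thin
detections survive, at the cost of fusing blobs closer than ~64 px —
then counted at 8-connectivity.  Tissue is detected by block-mean
downscaling, grayscale OD, Otsu, and hole filling; a slide whose OD
range is below 0.02 has no tissue.  The burden score is
count / tissue area × median area; the annotator analog substitutes
point-annotation counts over annotated ROI area.

Because the per-tile DAB segmentation min-max normalizes before Otsu,
a signal-free tile would otherwise amplify quantization residue into
spurious foreground; tiles whose DAB range is below 0.1 OD (an order of
magnitude under stained-object contrast) are therefore treated as
degenerate and yield empty masks.  This floor is what makes a
zero-tangle slide score exactly 0.

## Numerical and interface choices

- Coordinates are 0-based, (x, y) = (column, row), half-open; boxes are
  (xmin, ymin, xmax, ymax) with pixel-area IOU semantics.
- Rotated-ROI corners are corner *pixel centers*, clockwise from the
  ROI's top-left; extraction slices the minimal axis-aligned bounding
  region then resamples with bilinear interpolation (angle 0 degenerates
  to an exact slice; the point transform is the exact inverse, so
  global→local→global round trips are sub-pixel).
- Chunked storage uses Zarr with 5000-px chunks; byte identity is the
  contract, the compression codec is not.
- Super-tile grids use rounding (21,236 / 4247 ≈ 5.0002 → 5 columns)
  with the final row/column absorbing the remainder — the only
  remainder rule that tiles a full-size ROI into exactly fifteen
  4247×3560 frames.  Re-annotation is additive only.
- Degenerate statistics fail loudly: single-class AUROC, constant-grade
  Spearman, and zero tissue area raise; zero-denominator scores return
  0 with a warning.

## Problem sizes

Tests run the full pipeline on 2048² ROIs with 5 tangles each (20 ROIs
for the parameter-recovery check) and 3072² synthetic slides — sizes at
which every stage, including whole-slide sweeps, behaves identically to
production scale modulo the number of tiles processed.

## Known limitations

- The classical DAB-threshold predictor stands in for a learned
  segmenter; it is exact on synthetic scenes but would not separate
  tangles from other tau-positive structures in real tissue.
- Block-max downscaling before blob counting fuses detections closer
  than the downscale factor; counts are a lower bound in dense regions.
- Tissue detection assumes white glass vs. stained tissue; faint or
  unstained tissue below the OD floor is not counted as area.
- Proprietary scanner formats are out of scope; ingestion accepts
  arrays, PNG/TIFF, or pre-converted chunked stores.
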