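# Methods

This note documents the models, conventions, and numerical choices behind
pixikit, and what the synthetic-data tests do and do not establish.

## Project model and staged edits

The project store keeps committed entity tables (images, annotations, kinds,
categories) plus a change set of per-entity field diffs. Reads apply the
diffs on the fly, so measurement and training always see the researcher's
working state; `commit()` folds the diffs into the committed tables and
`revert()` drops them, restoring the committed state exactly. Staging is
per-field (not whole-entity copies), which keeps the change set proportional
to what was actually edited. There is no multi-level undo: one change set,
one revert.

Coordinates are 0-based, half-open, x right / y down — the COCO convention —
everywhere, including bounding boxes `(x, y, width, height)`. Partitions
form the closed set {train, validation, inference, unassigned} and apply to
both images and objects. Every kind owns a reserved "Unknown" category that
cannot be deleted; it is the explicit unlabeled pool the classifier trains
against. Pixel and mask buffers are made read-only on ingestion, so the
measurement cache can key on buffer identity: a measurement is recomputed
only when an entity's underlying array is replaced.

## Annotation operators

All operators act on one z-slice, a `(channel, y, x)` array in [0, 1], and
return full-extent boolean masks.

- **Rasterization** uses the pixel-center inside test (the pixel at row r,
  column c has center (c+0.5, r+0.5)) and the even-odd rule for polygons.
  This makes shape→mask→tight-crop→reinflate an exact round trip.
- **SLIC superpixels** are implemented directly as localized k-means in
  (color, position) space: seeds on a deterministic regular grid with
  spacing S = sqrt(hw/n), distance d = d_color + (compactness/S)·d_space,
  assignment restricted to 2S windows, 5 iterations, no random restarts.
  Defaults: compactness 10. The deterministic grid initialization is load-
  bearing: it guarantees a usable partition at small segment counts (e.g.
  n=2 on a small image yields two centers, one per half), where grid
  heuristics tied to sqrt-spacing alone can collapse to a single center.
  Every requested label is guaranteed nonempty (an empty label steals its
  nearest pixel from a label that keeps ≥ 2).
- **Quick-select** returns the union of whole superpixels containing the
  seed points — never a partial superpixel.
- **Flood fill** grows the 4-connected region whose Euclidean color
  distance (over channels) to the seed color is ≤ tolerance. Implemented as
  a global threshold on the distance image followed by connected-component
  selection, which is equivalent to breadth-first growth for a fixed seed
  color and vectorizes well.
- **Threshold tool** selects pixels inside a bounding box whose channel-mean
  intensity is below (default) or above the threshold. The polarity switch
  exists because bright-object selection is the common fluorescence case.

## Measurements

Geometry is pixel-based and defined for objects only (it needs a mask; it is
rejected for the "Image" kind):

- area A = foreground pixel count; bounding-box area = tight-box w·h;
- perimeter P = inner-boundary count: foreground pixels with at least one
  background *or out-of-extent* 4-neighbor;
- extent A/A_BB; equivalent diameter 2√(A/π); PED P/π;
  sphericity S = 2√(πA)/P; compactness C = 1/S.

Because the pixel perimeter of a rasterized disk undershoots the continuous
circumference, rasterized circles have S slightly above 1; S = C = 1 holds
exactly (to machine precision) for analytic inputs (A = πr², P = 2πr), and
`derived_geometry` deliberately accepts non-integer inputs so that
closed-form checks are exact. Conversely C > 1 indicates irregularity;
the plus-sign fixture (area 45, perimeter 28) gives C ≈ 1.18.

Intensity statistics are per channel; for objects, only pixels under the
mask on the annotation's z-plane are used. The MAD is
median(|xᵢ − median(x)|). Quartiles are nearest-rank: the value at 1-based
sorted rank ⌊qn⌋+1, i.e. the smallest pixel value such that a fraction q of
pixels lie strictly below whenever qn is integral; no interpolation, so the
quartile is always an attainable pixel value. The standard deviation is
population (divide by n). Histogram bins are half-open [lo, hi) with the
final bin closed, so counts always sum to the number of items.

Split summaries (total, median, std per measurement and channel) are
computed from the per-item rows and are invariant to item order.

## Classifier

`simple_cnn` is two 3×3 convolution blocks (8 and 16 filters, ReLU, 2×2 max
pool) followed by global average pooling and a dense softmax — deliberately
small enough to train on one CPU in seconds. `transfer_head` freezes the
convolutional stack (any feature extractor can stand in; tests use the
seeded random stack, so no pretrained download is needed) and trains only
the final dense layer; frozen parameters are verifiably unchanged by
training. Inputs are bilinearly resized to the configured extent and
per-image min-max scaled to [0, 1].

Optimization is SGD with momentum 0.9 at a fixed learning rate (default
0.05). The optimizer velocity is part of the serialized training state, so
`fit(a)` followed by `fit(b)` is bit-identical to `fit(a+b)`: one seed
drives the train/validation split, weight initialization, and per-epoch
shuffling, with each epoch reseeded from (seed, epoch-index) so resumed runs
replay the same shuffle sequence. This is the contract behind the
human-in-the-loop workflow: label → train → predict the unlabeled pool →
stage the predictions for review → correct → resume on the expanded set.
Predictions staged by `hitl_round` are ordinary staged edits, reviewable and
revertable like any other.

The train/validation split is stratified by category (sklearn) and falls
back to a plain random split with a warning when a class has a single item.
Evaluation (confusion matrix, per-class precision/recall/F1, accuracy,
macro-F1) goes through scikit-learn and is cross-checked in the tests
against a direct counting implementation. Both per-class and macro F1 are
reported, since a single "F1" is ambiguous for multi-class problems.

## Synthetic data: what it emulates, what it does not

The scene generator renders disks, rectangles, and plus signs with known
closed-form geometry, optional additive Gaussian noise clipped to [0, 1],
and exact ground-truth masks. The class dataset draws images whose classes
differ in mean intensity (defaults 0.3 vs 0.7) and in the frequency of a
sinusoidal grating (2 vs 6 cycles, amplitude 0.08, random phase), with noise
σ = 0.1 — 50 images per class is the default study size. Because per-image
min-max standardization removes the mean-intensity cue, the CNN must learn
the texture difference; that it does so to macro-F1 ≥ 0.9 within 30 epochs
shows the training loop optimizes and resumes correctly, **not** that the
architecture would reach any particular score on real microscopy data:
the fixtures have no cell morphology, no optics (PSF, vignetting), no
staining variability, and low Bayes error by construction.

Problem sizes used throughout the tests (48×48 scenes, 32×32 training
images, ≤ 100-image datasets, ≤ 30 epochs) were chosen as the smallest
scales at which every contract is meaningfully exercised.

## Interchange formats

- **COCO**: masks are traced into polygons at pixel-corner resolution
  (directed boundary edges chained into closed loops; holes become
  additional loops, filled with the even-odd rule). Since vertices are pixel
  corners, rasterizing back with the pixel-center test reproduces the mask
  bit-exactly — round-trip IoU is 1.0, comfortably above the documented
  ≥ 0.99 contract, and `area` equals the pixel count exactly. Integer ids
  are assigned deterministically (sorted original ids, 1-based); original
  string ids travel in a `pixikit_id` field.
- **Mask exports**: labeled-instance (uint16, instance index per pixel,
  later instance wins on overlap with a warning), binary-instance (one file
  per object), binary-semantic (per-category union).
- **Zarr archive**: schema version "1", whole-plane chunks, committed state
  only; loading a mismatched schema version fails before any partial state
  is constructed.
- **Model format**: a JSON description (layer list with shapes and trainable
  flags, class names, config, history, shard manifest) plus little-endian
  float64 weight shards covering parameters *and* optimizer velocities. The
  manifest's byte counts are validated against the shard before loading.
- **TIFF hyperstacks** are interpreted channel-fastest (c within z) with the
  channel count declared at import; a page count not divisible by the
  declared channels is an error, not a guess. DICOM support is restricted to
  single-frame grayscale with uncompressed transfer syntaxes; rescale
  slope/intercept are applied and intensities scaled by BitsStored.

## Known limitations

- Object intensity uses only the annotation's z-plane, not the full stack.
- Pixel-perimeter compactness is not guaranteed > 1 for every non-circular
  mask (digitization can undershoot); the claim is about irregular shapes
  like the plus fixture, where it holds with margin.
- The SLIC implementation targets correctness and determinism at annotation
  scale (hundreds of segments), not large-image throughput.
- No undo history beyond single-level revert; no concurrent editing.
- The CNN is CPU-scale by design; it makes no claim to state-of-the-art
  accuracy on real datasets.
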