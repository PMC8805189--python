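# Methods

## Problem and approach

Synaptic vesicles are ~30-55 nm membrane-bound organelles that appear in
transmission-EM micrographs as dark elliptical rings with a brighter lumen.
`vesiclepick` detects and localizes them in 2D micrographs and reports, per
vesicle, the coordinates, the nearest-neighbor distance (nnd, nm) and an
elliptical area estimate (nm²).

The pipeline is a sliding-window detector built from two patch classifiers:

1. **Rescaling.** The input is resampled bilinearly to the native training
   resolution of 2.27 nm/px (dimensions scale by `pixel_size / 2.27`); an
   optional exclusion mask is resampled nearest-neighbor.
2. **Probability map.** The image is zero-padded by 20 px per side and the
   first classifier scores the 40x40 patch spanning −20..+19 around every
   pixel on a stride-4 grid. Masked pixels get probability 0.
3. **Postprocessing.** Probabilities below 0.5 are zeroed; the grid is
   resized bilinearly to the original image shape, smoothed with a
   normalized 3x3 box filter, and scaled to 0-255.
4. **Segmentation.** Nonzero pixels are labeled into 4-connected components
   (squared connectivity 1). For each component, local maxima of the map
   are retained greedily in descending value subject to a mutual distance
   > 34 nm (roughly one vesicle diameter); the retained count k seeds a
   deterministic, peak-initialized k-means that splits the component into k
   clusters. Clusters with a footprint below the pixel-size dependent area
   threshold (330 nm² at native resolution, rising stepwise to 716 nm² for
   pixel sizes ≥ 6.3 nm) are discarded.
5. **Refinement.** Each surviving cluster center is re-evaluated by a
   second classifier on an 80x80 patch (image zero-padded by 40 px);
   negatives are discarded. This pass exists to remove false positives on
   vesicle-like texture inside mitochondria and along membranes.

All cluster geometry lives in original-image pixels: the map is resized to
the original input shape, so a map pixel is an image pixel and footprint
areas use the input pixel size. Only the refinement crop maps centers to
the rescaled image.

## Classifier architecture and training

Both classifiers share one topology: four 7x7 convolutions (each input
zero-padded by 2, so a side shrinks by 6 per layer), one 2x2 max pool,
then three fully connected layers; ReLU activations throughout, dropout
between the last two convolutions (0.25) and between the FC layers (0.5).
For a 40 px input the conv sides are 38, 36, 34, 32, pooled to 16
(flattened size `C·16²`); for 80 px they are 78, 76, 74, 72, pooled to 36.
Training uses softmax cross-entropy and Adam, learning rate 2e-4 for the
first classifier and 4e-4 for the refinement one. Weights come from the
epoch with the best test F1 among epochs followed by three consecutive
test-loss increases, falling back to the global F1 maximum.

The published filter widths (16-32-64-128, FC 512-128-2) are the
`ClassifierConfig` defaults and are exercised by the shape tests. Training
and end-to-end evaluation use the package's *desk-scale* preset
(6-12-12-12 filters, FC 64-32-2, 8 epochs for the first classifier and 5
for the refinement one): the synthetic task separates cleanly at this
capacity, and the narrow net trains from scratch on one CPU in minutes.
FC widths, dropout rates, batch size (64 / 16) and epoch budget are
package choices, exposed in the config.

The network layers (conv/pool/dense, Adam, dropout) are implemented
directly on numpy with an im2col formulation; backprop is verified against
finite differences in the test suite.

Augmentation during training: rotation uniform in ±10° (reflect padding),
brightness and contrast jitter of ±20%, and additive Gaussian noise
components (σ 0.1 with probability 0.2 plus σ 0.05 with probability 0.1
for the first classifier; σ 0.1 with probability 0.1 for the refinement
one). "10% rotation" is interpreted as ±10 degrees; saturation jitter is
meaningless on single-channel images and is not modeled.

## Morphometry

**nnd** is the shortest Euclidean distance from each detection to any
other, in nm; a single detection has no neighbor and reports a missing
value.

**Area** comes from exhaustive dark-ring template matching on the rescaled
(2.27 nm/px) image, so nm² values are resolution-independent: all 34
axis-aligned elliptical outlines with semi-axes a, b ∈ [7, 12] px and
|a−b| ≤ 4 px (thickness 3 px), each shifted over the full ±3 px integer
neighborhood, are scored on the 40x40 patch whose (row 20, col 20) pixel
is the detection. The score is the mean intensity under the outline plus
0.03 times the population SD (n = 4) of the four per-quadrant means of the
masked values — darker and more symmetric is better — and the global
minimum wins, with ties broken by smaller area, then smaller shift.
`area = a·b·π·pixel_area`. A flag restricts shifts to the axes for the
literal "up, down, left, right" reading.

A pixel belongs to a ring iff its radial distance from the ellipse
boundary (measured along the ray from the center) is at most 1.5 px. The
synthetic generator uses the same rasterization, which is what makes exact
recovery on noise-free images a meaningful test. Ellipses are axis-aligned
only; rotated vesicles are fitted by the nearest axis-aligned template
(documented limitation). Patches at image borders are replicate-padded so
the darkness score is not biased toward dark zero padding.

## Evaluation protocol

Predictions and ground truth are paired greedily with removal: loop over
ground truths in row-major (y, x) order, pair each with its nearest
still-unpaired prediction within 28.89 nm (the lower bound of a vesicle
diameter); unpaired ground truths are false negatives. The mirrored loop
over predictions yields false positives. The true-positive count is the
mean of the two passes (possibly fractional) and feeds the standard
precision/recall/F1 formulas. A no-removal variant (one target may pair
with several sources) is available behind a flag. Annotator comparison
runs the scoring both ways and averages the metrics. SEM uses n−1.

## Synthetic data

The generator emulates what the detector actually keys on: dark elliptical
membrane rings (3 px thick, semi-axes 7-12 px ⇒ diameters ~32-55 nm at
2.27 nm/px) with lumen brighter than background (defaults 0.75 / 0.55 /
membrane 0.25 on the 0-1 scale), placed by rejection sampling (1000
attempts per object, error on failure) with centers at least one maximal
vesicle diameter (54.5 nm) apart by default. Distractors emulate the two
dominant false-positive sources: mitochondria-like textured blobs
(100-400 nm across, with striations) and straight dark membranes (3 px),
placed clear of vesicle centers. Contrast is applied about the image mean
before Gaussian pixel noise (default σ 0.05); values are clipped to [0,1].
An optional black exclusion rectangle emulates the masking convention.

Patch datasets derive from these images at a negative:positive ratio of
2.84 (first classifier) / 2.18 (refinement). Positives are windows
centered on vesicle centers with ±2 px jitter (matching the stride-4
evaluation grid). Negatives keep at least one minimal vesicle diameter
(~30 nm = 13 px) between window center and any vesicle center, and are a
mix designed around how a sliding-window detector actually fails:

- *hard negatives* centered just beyond the exclusion radius, so an
  off-center vesicle in view is an explicit "no" — this is what makes the
  probability map peak at vesicle centers instead of blanketing them;
- *edge negatives* cut from the zero-padded image with centers near the
  border, because inference pads the image and a classifier never shown
  part-zero windows fires along the edges;
- distractor-centered windows and uniform background;
- ~10% all-black patches (the exclusion-mask convention).

The refinement classifier's dataset shifts the boundary to its task —
"is a vesicle centered here, give or take the detector's localization
scatter": positives jittered ±6 px, negatives from 16 px out, straddling
the 28.89 nm pairing radius. On top of the sampled patches, the default
training recipe (`train_models`) *mines* refinement examples from the
trained first stage itself: it runs detection through clustering and size
thresholding on extra micrographs and labels each candidate by its
distance to ground truth (within the pairing radius → positive, beyond
16 px → negative; the thin band between is ambiguous and dropped). Mined
candidates match the distribution the refinement classifier actually
faces, which sampling around ground-truth centers cannot; they also join
the test set that drives epoch selection, while patch-level quality
metrics are reported on the cleanly-sampled patches whose labels are
unambiguous. The whole sampling and mining scheme is a package design
choice; workflows built on hand-labeled patches have no need to specify
one.

Training micrographs cycle through contrast factors 0.5–1.5 (five levels),
emulating the appearance spread between preparation protocols (cryo- vs
chemical fixation) that real EM training sets contain; this is what makes
detection performance flat across the same contrast range at test time.

What the generator does **not** model: 2D projection of 3D sections
(partial, blurry vesicles), docked/omega shapes, stain granularity,
correlated noise, rotated ellipses. Passing end-to-end tests therefore
demonstrate that the pipeline machinery recovers its own model class, not
EM-grade performance; on real micrographs the pretrained-at-full-width
configuration and real labeled patches would be needed.

## Problem sizes and defaults

Single-CPU budgets shaped the default experiment sizes, chosen once:

- training: 16 micrographs (512², 25 vesicles) ⇒ ~1500 40-px patches at
  ratio 2.84; refinement uses 8 of those images ⇒ ~600 80-px patches at
  ratio 2.18;
- end-to-end evaluation: 10 held-out 256² micrographs with 12 vesicles and
  4 distractors each (the 512²/25-vesicle density);
- touching-pair fixtures: 256², 14 vesicles, minimum center separation
  46 nm, no distractors — close enough that probability blobs merge while
  peaks stay > 34 nm apart;
- robustness: noise σ ∈ {0, 0.3} and contrast ∈ {0.5, 1.0, 1.5} on two
  held-out images.

## Numerical choices

- k-means: peak-initialized, ≤ 100 Lloyd iterations, assignment ties to
  the lower cluster index — fully deterministic; empty clusters keep their
  previous center.
- Peak plateaus (ties under the 3x3 maximum filter) collapse to their
  centroid; candidate order is by descending value, then (row, col).
- Refinement centers round half-up to integer pixels.
- The size-threshold table keys are lower bounds; the largest applicable
  entry wins and the table saturates at 716 nm².
- Probability-map stages keep their value ranges ([0,1] before scaling,
  [0,255] after); the stride-4 grid has `floor((dim−1)/4)+1` cells per
  axis.
- Values below 1e-9 are zeroed after the box smoothing: the running-sum
  filter leaves ~1e-15 arithmetic residue on exact-zero pixels downstream
  of every blob, which would otherwise bridge distant components and
  create spurious flat "peaks".
- All randomness flows through explicit integer seeds (numpy Generator);
  identical config + seed reproduces images, patches, training and
  detections bit-for-bit on a platform.

## Known limitations

- No rotated or sub-pixel ellipse fits; no dense-core/clear classification.
- No 3D linking across serial sections; batches must share one pixel size.
- The numpy CNN is CPU-only and unbatched across images; it is sized for
  desk-scale experiments, not for training on large EM corpora.
- The synthetic domain is easier than real EM; reported synthetic F1
  values upper-bound what the same configuration would do on micrographs.
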