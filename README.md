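# vesiclepick

Automated detection and morphometry of synaptic vesicles in 2D
transmission-EM micrographs.

Synaptic vesicles (~30-55 nm organelles storing neurotransmitter) appear
in EM as dark elliptical membrane rings with a brighter lumen. Counting
and measuring the hundreds to thousands of them in a presynaptic terminal
by hand is slow and subjective. `vesiclepick` automates it for
neuroscientists analyzing presynaptic ultrastructure: it takes grayscale
TIFF/PNG micrographs with a known pixel size and returns, per vesicle, the
coordinates, the nearest-neighbor distance (nnd, nm) and an elliptical
area estimate (nm²).

## Method

A CNN patch classifier slides over the image (40×40 patches at 2.27 nm/px,
stride 4, zero padding 20 px) and yields a per-pixel vesicle probability
map *P(x)*. The map is thresholded at 0.5, resized to the image, smoothed
with a 3×3 box filter and scaled to 0–255; 4-connected components are
split into single vesicles by k-means, with *k* set by the number of map
peaks more than 34 nm apart; clusters smaller than the pixel-size
dependent area threshold (330 nm² at native resolution) are dropped; and a
second CNN re-examines each candidate on an 80×80 patch to reject false
positives (mitochondria, membranes). Detection quality is scored by 1–1
greedy pairing of predictions and annotations within 28.89 nm:

```
precision = TP / (TP + FP)    recall = TP / (TP + FN)
F1 = 2 · precision · recall / (precision + recall)
```

with TP averaged over the two pairing passes. Vesicle area comes from
exhaustive dark-ring template matching (semi-axes 7–12 px, |a−b| ≤ 4,
±3 px shifts, asymmetry-penalized darkness score); `area = a·b·π·px²`.

A seeded synthetic micrograph generator (dark rings + lumen + distractor
organelles + noise) provides exact ground truth, so the whole pipeline can
be trained and evaluated end to end without external data. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
import vesiclepick as vp
from vesiclepick.pipeline import train_models, detect_and_measure

# train both classifiers from scratch on synthetic micrographs (~minutes)
model_first, model_refine, info = train_models(seed=1)

# held-out synthetic image with known ground truth
config = vp.SynthConfig(image_height_px=256, image_width_px=256,
                        n_vesicles=12, n_distractors=4, seed=777)
micrograph, truth = vp.generate_micrograph(config)

detections = detect_and_measure(micrograph, model_first, model_refine)
pred = np.array([[d.x_px, d.y_px] for d in detections])
report = vp.pair_and_score(truth[["x_px", "y_px"]].to_numpy(), pred,
                           micrograph.pixel_size_nm)
print(len(detections), round(report.f1, 3))
print(round(detections[0].nnd_nm, 1), round(detections[0].area_nm2, 1))
```

Printed output from this exact script (seed 1):

```
12 1.0
103.6 1456.9
```

All 12 planted vesicles were found with no false positives (F1 = 1.0
under the 28.89 nm pairing rule); the first vesicle's nearest neighbor is
103.6 nm away and its fitted ellipse covers 1456.9 nm² — a ~43 nm
diameter vesicle, mid-range for the simulated 32–55 nm population. The
`examples/` directory holds
runnable scripts for each capability (simulation, morphometry, scoring,
training + detection, robustness sweeps).

Shell use mirrors the library:

```bash
vesiclepick simulate --seed 1 --n-images 2 --out-dir sim/
vesiclepick detect --pixel-size 2.27 --weights-first first.npz \
    --weights-refine refine.npz --out results/ sim/*.tif
```

`detect` writes a summary table plus one CSV per image
(`vesicle_id, x_px, y_px, nnd_nm, area_nm2`), optionally as an XLSX
workbook; `vesiclepick correct` applies proof-reading edits (add/remove
detections) with automatic nnd/area recomputation.

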