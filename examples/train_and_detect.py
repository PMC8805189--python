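"""Train both patch classifiers from scratch on synthetic data, then run
full-image detection with morphometry on a held-out micrograph.

This is the whole pipeline end to end: sliding-window probability map
(40x40 patches, stride 4), thresholding/resizing/smoothing, 4-connected
component labeling, peak-guided k-means splitting, the 330 nm^2 size
threshold, the 80x80 refinement pass, then nnd and area per vesicle.
Takes several minutes on one CPU; reduce the image counts to go faster.
"""

import logging

import numpy as np

import vesiclepick as vp
from vesiclepick.pipeline import detect_and_measure, train_models

logging.basicConfig(level=logging.INFO, format="%(message)s")

model_first, model_refine, info = train_models(
    n_train_images=8, n_test_images=2, seed=1
)
print(f"first classifier:  best epoch {info['best_epoch_first']}, "
      f"patch F1 {info['history_first'].f1[info['best_epoch_first']]:.3f}")
print(f"refinement:        best epoch {info['best_epoch_refine']}, "
      f"patch F1 {info['history_refine'].f1[info['best_epoch_refine']]:.3f}")

heldout = vp.SynthConfig(image_height_px=256, image_width_px=256,
                         n_vesicles=12, n_distractors=4, seed=777)
micrograph, truth = vp.generate_micrograph(heldout)
detections = detect_and_measure(micrograph, model_first, model_refine)

print(f"\nground truth: {len(truth)} vesicles; detected: {len(detections)}")
pred = np.array([[d.x_px, d.y_px] for d in detections])
report = vp.pair_and_score(truth[["x_px", "y_px"]].to_numpy(), pred,
                           micrograph.pixel_size_nm)
print(f"precision={report.precision:.3f} recall={report.recall:.3f} "
      f"f1={report.f1:.3f} (28.89 nm pairing rule)")
print("\nper-vesicle output (first five):")
print(f"{'x_px':>7} {'y_px':>7} {'nnd_nm':>8} {'area_nm2':>9}")
for d in detections[:5]:
    print(f"{d.x_px:7.1f} {d.y_px:7.1f} {d.nnd_nm:8.2f} {d.area_nm2:9.1f}")
print("nnd = distance to the nearest other detection; area from the "
      "darkest elliptical ring template")
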