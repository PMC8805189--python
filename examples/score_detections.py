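"""Pairing-based detection scoring and inter-annotator comparison.

A prediction counts as a true positive when it can be 1-1 paired with a
ground-truth point within 28.89 nm (the lower bound of a vesicle
diameter).  Pairing runs twice - looping over ground truths, then over
predictions - and the true-positive count is the average of the two
passes.
"""

import numpy as np

import vesiclepick as vp

rng = np.random.default_rng(0)
truth = rng.random((30, 2)) * 500  # (x, y) pixel coordinates
# predictions: most truths slightly displaced, 3 missed, 4 spurious
pred = np.vstack([truth[:27] + rng.normal(0, 3, (27, 2)), rng.random((4, 2)) * 500])

report = vp.pair_and_score(truth, pred, pixel_size_nm=2.27)
print(f"tp={report.tp:.1f}  fp={report.fp}  fn={report.fn}")
print(f"precision={report.precision:.3f}  recall={report.recall:.3f}  "
      f"f1={report.f1:.3f}")
print("(fp counts predictions unpaired in the prediction loop, fn counts "
      "truths unpaired in the ground-truth loop)")

# two annotators who disagree on a few vesicles
annot_b = np.vstack([truth[:26], rng.random((3, 2)) * 500])
_, _, averaged = vp.compare_annotators(truth, annot_b, pixel_size_nm=2.27)
print(f"inter-annotator agreement (averaged both ways): "
      f"f1={averaged['f1']:.3f}")
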