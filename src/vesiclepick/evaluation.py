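"""Pairing-based scoring of predicted vs ground-truth vesicle coordinates,
plus the noise/contrast robustness harness.

A prediction and an annotation count as the same vesicle when they fall
within 28.89 nm of each other — the lower bound of a vesicle diameter.
Pairing is greedy with removal, run twice (looping over ground truths,
then over predictions); the true-positive count is the average of the two
passes, and precision/recall/F1 follow from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .micrograph import Micrograph

__all__ = [
    "MatchReport",
    "pair_and_score",
    "compare_annotators",
    "add_gaussian_noise",
    "adjust_contrast",
    "robustness_sweep",
    "MAX_PAIR_DISTANCE_NM",
]

log = logging.getLogger(__name__)

#: Pairing cap: the lower boundary of a synaptic-vesicle diameter.
MAX_PAIR_DISTANCE_NM = 28.89


@dataclass(frozen=True)
class MatchReport:
    """Detection-vs-truth scores for one image.

    ``tp`` is the average pair count of the two passes and may be
    fractional; ``fn`` counts ground truths unpaired in pass 1, ``fp``
    predictions unpaired in pass 2.  Undefined metrics are NaN.
    """

    tp: float
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    n_ground_truth: int
    n_predictions: int
    max_pair_distance_nm: float = MAX_PAIR_DISTANCE_NM


def _as_points(points) -> np.ndarray:
    arr = np.asarray(points, dtype=np.float64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    return arr.reshape(-1, 2)


def _row_major(points: np.ndarray) -> np.ndarray:
    """Deterministic input order: sort by (y, x)."""
    if len(points) == 0:
        return points
    order = np.lexsort((points[:, 0], points[:, 1]))
    return points[order]


def _greedy_pairs(
    sources: np.ndarray,
    targets: np.ndarray,
    cap_px: float,
    reuse_targets: bool = False,
) -> int:
    """Loop over sources in order; pair each with its nearest (available)
    target within the cap.  Returns the number of pairs."""
    if len(sources) == 0 or len(targets) == 0:
        return 0
    available = np.ones(len(targets), dtype=bool)
    pairs = 0
    for s in sources:
        d = np.hypot(targets[:, 0] - s[0], targets[:, 1] - s[1])
        if not reuse_targets:
            d = np.where(available, d, np.inf)
        j = int(np.argmin(d))
        if d[j] <= cap_px:
            pairs += 1
            available[j] = False
    return pairs


def pair_and_score(
    ground_truth_points,
    predicted_points,
    pixel_size_nm: float,
    max_pair_distance_nm: float = MAX_PAIR_DISTANCE_NM,
    reuse_targets: bool = False,
) -> MatchReport:
    """Two-pass greedy pairing and precision/recall/F1.

    Point sets are (n, 2) arrays of (x, y) pixel coordinates; distances
    are compared in nm.  Pass 1 loops over ground truths (unpaired ones
    are false negatives), pass 2 over predictions (unpaired ones are false
    positives); ``tp`` is the mean of the two pair counts.  With
    ``reuse_targets`` a target may pair with several sources within a pass
    (the literal no-removal reading).
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    gt = _row_major(_as_points(ground_truth_points))
    pred = _row_major(_as_points(predicted_points))
    cap_px = max_pair_distance_nm / pixel_size_nm

    pairs_gt = _greedy_pairs(gt, pred, cap_px, reuse_targets)
    pairs_pred = _greedy_pairs(pred, gt, cap_px, reuse_targets)
    tp = (pairs_gt + pairs_pred) / 2.0
    fn = len(gt) - pairs_gt
    fp = len(pred) - pairs_pred

    if len(gt) == 0 and len(pred) == 0:
        precision = recall = f1 = float("nan")
    else:
        precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
        recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
        if np.isnan(precision) or np.isnan(recall):
            f1 = float("nan")
        elif precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0
    return MatchReport(tp, int(fp), int(fn), float(precision), float(recall),
                       float(f1), len(gt), len(pred), max_pair_distance_nm)


def compare_annotators(
    annotations_a,
    annotations_b,
    pixel_size_nm: float,
    max_pair_distance_nm: float = MAX_PAIR_DISTANCE_NM,
) -> tuple[MatchReport, MatchReport, dict]:
    """Score two annotation sets against each other, both ways, and average.

    Returns (report with A as truth, report with B as truth, averaged
    precision/recall/F1).
    """
    a_truth = pair_and_score(annotations_a, annotations_b, pixel_size_nm,
                             max_pair_distance_nm)
    b_truth = pair_and_score(annotations_b, annotations_a, pixel_size_nm,
                             max_pair_distance_nm)
    averaged = {
        key: (getattr(a_truth, key) + getattr(b_truth, key)) / 2.0
        for key in ("precision", "recall", "f1")
    }
    return a_truth, b_truth, averaged


def add_gaussian_noise(img: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Add iid zero-mean Gaussian noise on the 0-1 scale, then clip."""
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative: {sigma}")
    img = np.asarray(img, dtype=np.float32)
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    return np.clip(img + rng.normal(0.0, sigma, size=img.shape), 0.0, 1.0).astype(
        np.float32
    )


def adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    """Stretch intensities about the image mean: mean + factor*(p - mean)."""
    if factor <= 0:
        raise ValueError(f"contrast factor must be positive: {factor}")
    img = np.asarray(img, dtype=np.float32)
    mean = img.mean()
    return np.clip(mean + factor * (img - mean), 0.0, 1.0).astype(np.float32)


def robustness_sweep(
    images_with_truth: list[tuple[Micrograph, np.ndarray]],
    pipeline,
    sigma_grid=(),
    contrast_grid=(),
    seeds=(0,),
    max_pair_distance_nm: float = MAX_PAIR_DISTANCE_NM,
) -> pd.DataFrame:
    """Detection performance under added noise and contrast changes.

    For every condition each image is perturbed (noise for the sigma grid,
    contrast for the contrast grid), detection is re-run and scored against
    ground truth; rows report mean and SEM (n-1 denominator) over
    image x seed replicates.  Sigma 0 / contrast 1 reproduce the
    unperturbed baseline exactly.

    ``images_with_truth`` pairs each micrograph with its (n, 2) array of
    ground-truth (x, y) coordinates; ``pipeline`` is a
    :class:`~vesiclepick.detector.DetectionPipeline`.
    """
    rows = []

    def run(condition_type, condition_value, perturb):
        scores = []
        for i, (mg, truth) in enumerate(images_with_truth):
            for seed in seeds:
                perturbed = Micrograph(perturb(mg.pixels, seed), mg.pixel_size_nm,
                                       mask=mg.mask, meta=dict(mg.meta))
                detections = pipeline.detect(perturbed)
                pred = np.array([[d.x_px, d.y_px] for d in detections])
                report = pair_and_score(truth, pred, mg.pixel_size_nm,
                                        max_pair_distance_nm)
                scores.append((report.precision, report.recall, report.f1))
        arr = np.asarray(scores, dtype=np.float64)
        row = {"condition_type": condition_type, "condition_value": condition_value,
               "n_images": len(images_with_truth)}
        for j, name in enumerate(("precision", "recall", "f1")):
            n = np.sum(~np.isnan(arr[:, j]))
            row[name] = float(np.nanmean(arr[:, j])) if n else float("nan")
            row[f"{name}_sem"] = (
                float(np.nanstd(arr[:, j], ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            )
        rows.append(row)

    for sigma in sigma_grid:
        run("noise_sigma", sigma, lambda px, seed, s=sigma: add_gaussian_noise(px, s, seed))
    for factor in contrast_grid:
        run("contrast_factor", factor, lambda px, seed, f=factor: adjust_contrast(px, f))
    return pd.DataFrame(rows)
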