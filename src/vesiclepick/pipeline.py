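"""High-level conveniences tying the stages together: train both
classifiers on synthetic data, run detection, and attach morphometry."""

from __future__ import annotations

import logging

import numpy as np

from .classifier import (
    AugmentationSpec,
    ClassifierConfig,
    build_classifier,
    restore_best_epoch,
    train_classifier,
)
from .detector import DetectionPipeline, DetectorParams, VesicleDetection, rescale_to_native
from .micrograph import Micrograph
from .morphometry import estimate_area, nearest_neighbor_distances
from .synthetic import (
    DEFAULT_NEGATIVE_RATIO,
    REFINE_NEGATIVE_RATIO,
    PatchDataset,
    SynthConfig,
    generate_micrograph,
    generate_patch_dataset,
)

__all__ = ["train_models", "mine_refinement_patches", "measure_detections",
           "detect_and_measure"]

log = logging.getLogger(__name__)


def mine_refinement_patches(
    model_first,
    images,
    params: DetectorParams = DetectorParams(),
    positive_radius_px: float = 28.89 / 2.27,
    negative_radius_px: float = 16.0,
) -> PatchDataset:
    """Refinement training patches mined from first-stage candidates.

    Runs the detector through clustering and size thresholding (no
    refinement) on micrographs with ground truth and cuts the 80x80 patch
    at every candidate center: a candidate within the pairing radius of a
    true vesicle is a positive (accepting it yields a true positive
    downstream), one beyond ``negative_radius_px`` a negative; the thin
    band between is ambiguous and dropped.  This matches the refinement
    classifier's training distribution to what it actually sees in the
    pipeline, which patch sampling around ground-truth centers cannot do.
    """
    from .detector import (
        apply_size_threshold,
        compute_probability_grid,
        count_peaks,
        label_components,
        postprocess_map,
        split_component,
    )

    side = params.refine_patch_side
    patches, labels = [], []
    for mg, truth in images:
        rescaled, factor = rescale_to_native(mg)
        grid = compute_probability_grid(rescaled, model_first, params)
        pmap = postprocess_map(grid, mg.shape, params)
        clusters = []
        for component in label_components(pmap):
            k = count_peaks(component, pmap, mg.pixel_size_nm, params)
            clusters.extend(split_component(component, k, pmap))
        clusters = apply_size_threshold(clusters, mg.pixel_size_nm, params)
        gt = truth[["x_px", "y_px"]].to_numpy(dtype=float)
        padded = np.pad(rescaled.pixels, params.pad_px_refine)
        for cluster in clusters:
            x, y = cluster.center_xy
            d = np.hypot(gt[:, 0] - x, gt[:, 1] - y).min() if len(gt) else np.inf
            if d <= positive_radius_px:
                label = 1
            elif d >= negative_radius_px:
                label = 0
            else:
                continue
            ry = int(np.floor(y * factor + 0.5))
            rx = int(np.floor(x * factor + 0.5))
            patches.append(padded[ry : ry + side, rx : rx + side])
            labels.append(label)
    if not patches:
        raise ValueError("no candidates mined; is the first classifier trained?")
    return PatchDataset(np.stack(patches), np.array(labels), side)


def _concat_datasets(a: PatchDataset, b: PatchDataset, seed: int) -> PatchDataset:
    patches = np.concatenate([a.patches, b.patches])
    labels = np.concatenate([a.labels, b.labels])
    order = np.random.default_rng(seed).permutation(len(labels))
    return PatchDataset(patches[order], labels[order], a.side_px, a.pixel_size_nm)


def train_models(
    n_train_images: int = 16,
    n_test_images: int = 4,
    n_refine_images: int | None = None,
    n_mining_images: int = 8,
    synth_config: SynthConfig = SynthConfig(),
    mining_config: SynthConfig | None = None,
    first_config: ClassifierConfig | None = None,
    refine_config: ClassifierConfig | None = None,
    seed: int = 0,
):
    """Train first and refinement classifiers from scratch on synthetic data.

    Micrographs are generated from ``synth_config`` with distinct seeds,
    patch datasets derived at the two class ratios (2.84 for the first
    classifier, 2.18 for the refinement one), both networks trained with
    their default augmentation, and the best epoch restored per the
    F1/loss-rise rule.  The refinement classifier additionally trains on
    candidates *mined* from the trained first stage (see
    :func:`mine_refinement_patches`), so its accept/reject boundary is
    learned on the distribution it will face.  Returns
    ``(model_first, model_refine, info)`` where ``info`` carries the
    histories and patch-set sizes.
    """
    if first_config is None:
        first_config = ClassifierConfig.desk_scale(40, seed=seed)
    if refine_config is None:
        refine_config = ClassifierConfig.desk_scale(80, seed=seed + 1)
    # training micrographs cycle through contrast levels, emulating the
    # appearance spread between preparation protocols (cryo- vs chemical
    # fixation) that real training sets contain; the endpoints span the
    # contrast range transmission EM plausibly produces
    contrast_cycle = (0.5, 0.75, 1.0, 1.25, 1.5)
    train_images = [
        generate_micrograph(synth_config.with_(
            seed=seed * 1000 + i,
            contrast_factor=synth_config.contrast_factor * contrast_cycle[i % 5],
        ))
        for i in range(n_train_images)
    ]
    test_images = [
        generate_micrograph(synth_config.with_(seed=seed * 1000 + 500 + i))
        for i in range(n_test_images)
    ]

    train40 = generate_patch_dataset(train_images, 40, DEFAULT_NEGATIVE_RATIO,
                                     seed=seed + 11)
    test40 = generate_patch_dataset(test_images, 40, DEFAULT_NEGATIVE_RATIO,
                                    seed=seed + 12)
    model_first = build_classifier(first_config)
    hist_first, snaps = train_classifier(
        model_first, train40, test40, first_config, AugmentationSpec.first_default()
    )
    best_first = restore_best_epoch(model_first, hist_first, snaps)

    # The refinement classifier's job is "is a vesicle centered here":
    # its positives tolerate the cluster-center jitter the detector
    # produces (+-4 px), and its negatives start just outside the pairing
    # radius so off-center candidates are explicitly rejected.
    if n_refine_images is None:
        n_refine_images = max(2, n_train_images // 2)
    refine_kwargs = dict(jitter_px=6, min_negative_distance_px=16.0,
                         hard_negative_fraction=0.4, edge_negative_fraction=0.15)
    train80 = generate_patch_dataset(train_images[:n_refine_images], 80,
                                     REFINE_NEGATIVE_RATIO, seed=seed + 21,
                                     **refine_kwargs)
    test80 = generate_patch_dataset(test_images[: max(1, n_test_images // 2)], 80,
                                    REFINE_NEGATIVE_RATIO, seed=seed + 22,
                                    **refine_kwargs)
    test80_sampled = test80  # clean labels, for patch-level evaluation
    if n_mining_images > 0:
        if mining_config is None:
            mining_config = synth_config.with_(
                image_height_px=256, image_width_px=256,
                n_vesicles=max(4, round(
                    synth_config.n_vesicles * 256 * 256
                    / (synth_config.image_height_px * synth_config.image_width_px)
                ) * 2),
                n_distractors=max(2, synth_config.n_distractors // 2),
            )
        mining_images = [
            generate_micrograph(mining_config.with_(
                seed=seed * 1000 + 3000 + i,
                contrast_factor=mining_config.contrast_factor * contrast_cycle[i % 5],
            ))
            for i in range(n_mining_images)
        ]
        n_mine_test = max(1, n_mining_images // 4)
        mined_train = mine_refinement_patches(model_first,
                                              mining_images[n_mine_test:])
        mined_test = mine_refinement_patches(model_first,
                                             mining_images[:n_mine_test])
        log.info(
            "mined %d refinement candidates (%d positive) from %d images",
            len(mined_train) + len(mined_test),
            mined_train.n_positive + mined_test.n_positive, n_mining_images,
        )
        train80 = _concat_datasets(train80, mined_train, seed + 31)
        test80 = _concat_datasets(test80, mined_test, seed + 32)
    model_refine = build_classifier(refine_config)
    hist_refine, snaps = train_classifier(
        model_refine, train80, test80, refine_config, AugmentationSpec.refine_default()
    )
    best_refine = restore_best_epoch(model_refine, hist_refine, snaps)

    info = {
        "history_first": hist_first,
        "history_refine": hist_refine,
        "best_epoch_first": best_first,
        "best_epoch_refine": best_refine,
        "n_patches_first": len(train40) + len(test40),
        "n_patches_refine": len(train80) + len(test80),
        "test40": test40,
        # combined (sampled + mined) set drives epoch selection; the
        # sampled-only set has unambiguous labels for patch-level metrics
        "test80": test80,
        "test80_sampled": test80_sampled,
    }
    log.info(
        "trained first classifier (best epoch %d, F1 %.3f) and refinement "
        "classifier (best epoch %d, F1 %.3f)",
        best_first, hist_first.f1[best_first], best_refine, hist_refine.f1[best_refine],
    )
    return model_first, model_refine, info


def measure_detections(
    detections: list[VesicleDetection],
    mg: Micrograph,
    rescaled: Micrograph | None = None,
    scale_factor: float | None = None,
) -> list[VesicleDetection]:
    """Attach nearest-neighbor distance (nm) and elliptical area (nm2).

    nnd uses the reported original-image coordinates and pixel size; area
    is estimated on the rescaled 2.27 nm/px image so nm2 values are
    resolution independent.
    """
    if not detections:
        return detections
    if rescaled is None or scale_factor is None:
        rescaled, scale_factor = rescale_to_native(mg)
    points = np.array([[d.x_px, d.y_px] for d in detections])
    nnd = nearest_neighbor_distances(points, mg.pixel_size_nm)
    for d, dist in zip(detections, nnd):
        d.nnd_nm = float(dist) if np.isfinite(dist) else None
        fit = estimate_area(
            rescaled.pixels,
            (d.x_px * scale_factor, d.y_px * scale_factor),
            rescaled.pixel_size_nm,
        )
        d.area_nm2 = fit.area_nm2
    return detections


def detect_and_measure(
    mg: Micrograph,
    model_first,
    model_refine=None,
    params: DetectorParams = DetectorParams(),
    **detect_kwargs,
) -> list[VesicleDetection]:
    """Detection plus morphometry in one call."""
    pipeline = DetectionPipeline(model_first, model_refine, params)
    pmap, rescaled, factor = pipeline.probability_map(mg)
    detections = pipeline.detections_from_map(
        pmap, rescaled, factor, mg.pixel_size_nm, **detect_kwargs
    )
    return measure_detections(detections, mg, rescaled, factor)
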