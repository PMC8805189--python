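"""Full-image vesicle detection.

The pipeline, in order: rescale the input to the native 2.27 nm/px
resolution; slide the first classifier over the image (40x40 patches,
stride 4, after zero-padding by 20 px) to build a probability map;
threshold at 0.5, resize the map back to the input shape (bilinear),
smooth with a normalized 3x3 box filter and scale to 0-255; label
4-connected components; count probability peaks more than 34 nm apart
inside each component to choose k; split components by peak-initialized
k-means; drop clusters whose footprint area falls below the pixel-size
dependent threshold (330 nm2 at the native resolution); and re-evaluate
each surviving candidate with the refinement classifier on an 80x80 patch
(image zero-padded by 40 px).

All component/cluster geometry lives in original-image pixel coordinates:
the probability map is resized to the original input shape, so one map
pixel is one input pixel and footprint areas use the input pixel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .classifier import predict_proba
from .micrograph import NATIVE_PIXEL_SIZE_NM, Micrograph

__all__ = [
    "DetectorParams",
    "ProbabilityMap",
    "Component",
    "Cluster",
    "VesicleDetection",
    "rescale_to_native",
    "compute_probability_grid",
    "postprocess_map",
    "label_components",
    "count_peaks",
    "split_component",
    "apply_size_threshold",
    "refine_detections",
    "detect",
    "DetectionPipeline",
]

log = logging.getLogger(__name__)

_CONNECT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass(frozen=True)
class DetectorParams:
    """All tunables of the detection pipeline with their published values."""

    stride_px: int = 4
    pad_px_first: int = 20
    pad_px_refine: int = 40
    prob_cutoff: float = 0.5
    box_kernel: int = 3
    peak_min_distance_nm: float = 34.0
    base_area_threshold_nm2: float = 330.0
    area_threshold_table: tuple[tuple[float, float], ...] = (
        (2.3, 407.0), (3.3, 484.0), (4.3, 562.0), (5.3, 639.0), (6.3, 716.0),
    )
    refine_patch_side: int = 80
    first_patch_side: int = 40

    def __post_init__(self):
        if not (0 < self.prob_cutoff < 1):
            raise ValueError("prob_cutoff must be in (0, 1)")
        thresholds = [t for _, t in self.area_threshold_table]
        if thresholds != sorted(thresholds) or len(set(thresholds)) != len(thresholds):
            raise ValueError("area thresholds must increase with pixel size")

    def area_threshold(self, pixel_size_nm: float) -> float:
        """330 nm2 below 2.3 nm/px, else the largest table entry whose key
        does not exceed the pixel size (the table saturates at its end)."""
        threshold = self.base_area_threshold_nm2
        for key, value in self.area_threshold_table:
            if pixel_size_nm >= key:
                threshold = value
        return threshold


@dataclass
class ProbabilityMap:
    """Per-pixel vesicle likelihood with provenance."""

    values: np.ndarray
    stage: str  # grid | thresholded | resized | smoothed | scaled255
    stride_px: int = 4
    native_pixel_size_nm: float = NATIVE_PIXEL_SIZE_NM

    def __post_init__(self):
        valid = {"grid", "thresholded", "resized", "smoothed", "scaled255"}
        if self.stage not in valid:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class Component:
    """One 4-connected blob of the scaled255 map."""

    rows: np.ndarray
    cols: np.ndarray
    peaks: list[tuple[float, float]] = field(default_factory=list)  # (row, col)

    @property
    def size(self) -> int:
        return len(self.rows)


@dataclass
class Cluster:
    """One candidate vesicle: a subset of a component's pixels."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray | None = None  # map values, for the weighted center

    @property
    def size(self) -> int:
        return len(self.rows)

    @property
    def center_xy(self) -> tuple[float, float]:
        """Unweighted centroid of the member pixels (the default center)."""
        return float(self.cols.mean()), float(self.rows.mean())

    @property
    def weighted_center_xy(self) -> tuple[float, float]:
        """Probability-weighted centroid (optional alternative center)."""
        if self.values is None or self.values.sum() == 0:
            return self.center_xy
        w = self.values / self.values.sum()
        return float((self.cols * w).sum()), float((self.rows * w).sum())

    def center(self, weighted: bool = False) -> tuple[float, float]:
        return self.weighted_center_xy if weighted else self.center_xy

    def footprint_area_nm2(self, pixel_size_nm: float) -> float:
        return self.size * pixel_size_nm ** 2


@dataclass
class VesicleDetection:
    """One detected vesicle in original-image pixel coordinates."""

    x_px: float
    y_px: float
    cluster_size_px: int = 0
    nnd_nm: float | None = None
    area_nm2: float | None = None


def rescale_to_native(mg: Micrograph) -> tuple[Micrograph, float]:
    """Bilinear resample to 2.27 nm/px; the mask is resampled nearest.

    Returns the rescaled micrograph and the scale factor (rescaled pixels
    per original pixel).  Identity when the image is already native.
    """
    factor = mg.pixel_size_nm / NATIVE_PIXEL_SIZE_NM
    if factor == 1.0:
        return mg, 1.0
    h, w = mg.shape
    new_shape = (int(round(h * factor)), int(round(w * factor)))
    if min(new_shape) < 40:
        raise ValueError(
            f"rescaled image {new_shape} is smaller than one 40 px patch"
        )
    pixels = resize(mg.pixels, new_shape, order=1, preserve_range=True,
                    anti_aliasing=False).astype(np.float32)
    mask = None
    if mg.mask is not None:
        mask = resize(mg.mask.astype(np.float32), new_shape, order=0,
                      preserve_range=True, anti_aliasing=False) > 0.5
    return Micrograph(pixels, NATIVE_PIXEL_SIZE_NM, mask=mask, meta=dict(mg.meta)), factor


def compute_probability_grid(
    mg: Micrograph,
    model_first,
    params: DetectorParams = DetectorParams(),
    batch_size: int = 64,
) -> ProbabilityMap:
    """Sliding-window positive-class probability on the stride-4 grid.

    The image is zero-padded by 20 px per side; the patch evaluated at
    pixel (r, c) spans rows/cols -20..+19 around it.  Pixels under the
    exclusion mask receive probability 0.
    """
    side = params.first_patch_side
    if model_first.meta.get("input_side_px", side) != side:
        raise ValueError(
            f"first classifier expects side {model_first.meta.get('input_side_px')}, "
            f"pipeline uses {side}"
        )
    pad = params.pad_px_first
    stride = params.stride_px
    h, w = mg.shape
    padded = np.pad(mg.pixels, pad)
    from numpy.lib.stride_tricks import sliding_window_view

    # window at (r, c) of the padded image is the patch evaluated at image
    # pixel (r, c); only pixels 0..dim-1 are evaluated, on the stride grid
    windows = sliding_window_view(padded, (side, side))[:h:stride, :w:stride]
    gh, gw = windows.shape[:2]
    assert gh == (h - 1) // stride + 1 and gw == (w - 1) // stride + 1
    flat = windows.reshape(-1, side, side)
    proba = predict_proba(model_first, flat, batch_size=batch_size)
    grid = proba.reshape(gh, gw)
    if mg.mask is not None:
        grid[mg.mask[::stride, ::stride]] = 0.0
    return ProbabilityMap(grid, stage="grid", stride_px=stride)


def postprocess_map(
    grid: ProbabilityMap,
    target_shape: tuple[int, int],
    params: DetectorParams = DetectorParams(),
) -> ProbabilityMap:
    """Cutoff at 0.5, bilinear resize to the image shape, 3x3 normalized
    box smoothing (reflect boundary), and conversion to the 0-255 range."""
    if grid.stage != "grid":
        raise ValueError(f"expected a grid-stage map, got {grid.stage!r}")
    values = np.where(grid.values >= params.prob_cutoff, grid.values, 0.0)
    values = resize(values, target_shape, order=1, preserve_range=True,
                    anti_aliasing=False)
    values = ndimage.uniform_filter(values, size=params.box_kernel, mode="reflect")
    # the running-sum box filter leaves ~1e-15 residue downstream of every
    # blob; left in place it bridges distant components and fakes peaks
    values[values < 1e-9] = 0.0
    return ProbabilityMap(values * 255.0, stage="scaled255", stride_px=grid.stride_px)


def label_components(pmap: ProbabilityMap) -> list[Component]:
    """Nonzero pixels partitioned into 4-connected components (squared
    connectivity 1: diagonal contact does not join)."""
    if pmap.stage != "scaled255":
        raise ValueError(f"expected a scaled255-stage map, got {pmap.stage!r}")
    labels, n = ndimage.label(pmap.values > 0, structure=_CONNECT4)
    components = []
    objects = ndimage.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        rows, cols = np.nonzero(labels[sl] == i)
        components.append(Component(rows + sl[0].start, cols + sl[1].start))
    return components


def count_peaks(
    component: Component,
    pmap: ProbabilityMap,
    pixel_size_nm: float,
    params: DetectorParams = DetectorParams(),
) -> int:
    """Number of probability peaks more than 34 nm apart inside a component.

    Local maxima (8-neighborhood; plateaus collapsed to their centroid) are
    kept greedily in descending map value subject to a mutual Euclidean
    distance strictly greater than ``34 / pixel_size_nm`` pixels.  At least
    one peak is always reported; the kept peaks are stored on the
    component.
    """
    if component.size == 0:
        raise ValueError("empty component")
    r0, r1 = component.rows.min(), component.rows.max()
    c0, c1 = component.cols.min(), component.cols.max()
    sub = pmap.values[r0 : r1 + 1, c0 : c1 + 1]
    member = np.zeros_like(sub, dtype=bool)
    member[component.rows - r0, component.cols - c0] = True
    masked = np.where(member, sub, -np.inf)
    is_max = (masked == ndimage.maximum_filter(masked, size=3, mode="constant",
                                               cval=-np.inf)) & member
    plateau_labels, n_plateaus = ndimage.label(is_max, structure=np.ones((3, 3), int))
    candidates = []
    for i in range(1, n_plateaus + 1):
        rr, cc = np.nonzero(plateau_labels == i)
        value = float(sub[rr[0], cc[0]])
        candidates.append((value, float(rr.mean()) + r0, float(cc.mean()) + c0))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    min_dist_px = params.peak_min_distance_nm / pixel_size_nm
    kept: list[tuple[float, float]] = []
    for value, r, c in candidates:
        if all(np.hypot(r - kr, c - kc) > min_dist_px for kr, kc in kept):
            kept.append((r, c))
    component.peaks = kept
    return max(len(kept), 1)


def split_component(component: Component, k: int, pmap: ProbabilityMap) -> list[Cluster]:
    """Partition a component into k clusters by peak-initialized k-means.

    k = 1 returns the whole component.  Lloyd iterations (at most 100) on
    the member pixel coordinates, initialized at the retained peaks;
    assignment ties break toward the lower cluster index, making the split
    fully deterministic.
    """
    if k <= 1:
        return [Cluster(component.rows.copy(), component.cols.copy(),
                        pmap.values[component.rows, component.cols])]
    if k > component.size:
        log.warning("k=%d exceeds component size %d; clamping", k, component.size)
        k = component.size
    points = np.stack([component.rows, component.cols], axis=1).astype(np.float64)
    if len(component.peaks) >= k:
        centers = np.array(component.peaks[:k], dtype=np.float64)
    else:  # degenerate: pad with farthest points
        centers = points[np.linspace(0, len(points) - 1, k).astype(int)].copy()
    assignment = None
    for _ in range(100):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assignment = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        if assignment is not None and np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for j in range(k):
            member = assignment == j
            if member.any():
                centers[j] = points[member].mean(axis=0)
    values = pmap.values[component.rows, component.cols]
    return [
        Cluster(component.rows[assignment == j], component.cols[assignment == j],
                values[assignment == j])
        for j in range(k)
        if (assignment == j).any()
    ]


def apply_size_threshold(
    clusters: list[Cluster],
    pixel_size_nm: float,
    params: DetectorParams = DetectorParams(),
) -> list[Cluster]:
    """Drop clusters whose footprint area is below the pixel-size threshold."""
    threshold = params.area_threshold(pixel_size_nm)
    return [c for c in clusters if c.footprint_area_nm2(pixel_size_nm) >= threshold]


def refine_detections(
    clusters: list[Cluster],
    img_rescaled: Micrograph,
    model_refine,
    scale_factor: float,
    params: DetectorParams = DetectorParams(),
    weighted_centers: bool = False,
) -> list[VesicleDetection]:
    """Second-look classification of every candidate on an 80x80 patch.

    Cluster centers (original-image pixels) are mapped to the rescaled
    image via ``scale_factor``, rounded half-up; the rescaled image is
    zero-padded by 40 px so corner patches are always complete.  Candidates
    classified negative are discarded.
    """
    if not clusters:
        return []
    side = params.refine_patch_side
    if model_refine.meta.get("input_side_px", side) != side:
        raise ValueError(
            f"refinement classifier expects side "
            f"{model_refine.meta.get('input_side_px')}, pipeline uses {side}"
        )
    pad = params.pad_px_refine
    padded = np.pad(img_rescaled.pixels, pad)
    patches = []
    for cluster in clusters:
        x, y = cluster.center(weighted_centers)
        ry = int(np.floor(y * scale_factor + 0.5))
        rx = int(np.floor(x * scale_factor + 0.5))
        patches.append(padded[ry : ry + side, rx : rx + side])
    proba = predict_proba(model_refine, np.stack(patches))
    detections = []
    for cluster, p in zip(clusters, proba):
        if p >= params.prob_cutoff:
            x, y = cluster.center(weighted_centers)
            detections.append(VesicleDetection(x, y, cluster.size))
    return detections


class DetectionPipeline:
    """The detection pipeline with cached intermediates.

    Lets callers compute the (expensive) probability map once and then run
    cheap downstream variants — with or without splitting, size threshold
    or refinement — which is how the stage ablations are evaluated.
    """

    def __init__(self, model_first, model_refine=None,
                 params: DetectorParams = DetectorParams()):
        self.model_first = model_first
        self.model_refine = model_refine
        self.params = params

    def probability_map(self, mg: Micrograph):
        """(scaled255 map at the original shape, rescaled image, scale factor)."""
        rescaled, factor = rescale_to_native(mg)
        grid = compute_probability_grid(rescaled, self.model_first, self.params)
        pmap = postprocess_map(grid, mg.shape, self.params)
        return pmap, rescaled, factor

    def detections_from_map(
        self,
        pmap: ProbabilityMap,
        rescaled: Micrograph,
        scale_factor: float,
        pixel_size_nm: float,
        refine: bool = True,
        split: bool = True,
        size_threshold: bool = True,
        weighted_centers: bool = False,
    ) -> list[VesicleDetection]:
        clusters: list[Cluster] = []
        for component in label_components(pmap):
            if split:
                k = count_peaks(component, pmap, pixel_size_nm, self.params)
            else:
                k = 1
            clusters.extend(split_component(component, k, pmap))
        if size_threshold:
            clusters = apply_size_threshold(clusters, pixel_size_nm, self.params)
        if refine:
            if self.model_refine is None:
                raise ValueError("refinement requested but no refinement model given")
            return refine_detections(
                clusters, rescaled, self.model_refine, scale_factor, self.params,
                weighted_centers=weighted_centers,
            )
        return [
            VesicleDetection(*c.center(weighted_centers), c.size) for c in clusters
        ]

    def detect(self, mg: Micrograph, refine: bool = True, split: bool = True,
               size_threshold: bool = True) -> list[VesicleDetection]:
        pmap, rescaled, factor = self.probability_map(mg)
        detections = self.detections_from_map(
            pmap, rescaled, factor, mg.pixel_size_nm,
            refine=refine, split=split, size_threshold=size_threshold,
        )
        log.info("detected %d vesicles", len(detections))
        return detections


def detect(
    mg: Micrograph,
    model_first,
    model_refine=None,
    params: DetectorParams = DetectorParams(),
    refine: bool = True,
    split: bool = True,
    size_threshold: bool = True,
) -> list[VesicleDetection]:
    """One-shot detection on a micrograph; see :class:`DetectionPipeline`."""
    pipeline = DetectionPipeline(model_first, model_refine, params)
    return pipeline.detect(mg, refine=refine, split=split, size_threshold=size_threshold)
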