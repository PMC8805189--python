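"""Synthetic EM-like micrographs with exact ground truth.

Transmission-EM images of presynaptic terminals show synaptic vesicles as
dark elliptical membrane rings (diameters roughly 30-55 nm) enclosing a
brighter lumen, on a mid-gray cytoplasmic background, surrounded by
confounders: mitochondria (large textured organelles) and straight
membranes.  This module emulates exactly those statistics on a pixel grid —
enough to train and exercise every pipeline stage with known ground truth,
while making no claim to a physical EM contrast model.

All geometry uses the same ring rasterization as the area-estimation
templates, so noise-free generated vesicles are exactly recoverable by
template matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._geometry import interior_mask, ring_mask
from .micrograph import NATIVE_PIXEL_SIZE_NM, Micrograph

__all__ = [
    "SynthConfig",
    "PatchDataset",
    "PlacementError",
    "generate_micrograph",
    "generate_patch_dataset",
]

log = logging.getLogger(__name__)

#: Default negative:positive patch ratio for the first classifier.
DEFAULT_NEGATIVE_RATIO = 2.84
#: Default negative:positive patch ratio for the refinement classifier.
REFINE_NEGATIVE_RATIO = 2.18

_MAX_ATTEMPTS = 1000  # rejection-sampling cap per object


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested objects."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic micrograph.

    Intensity levels are on the [0, 1] scale; the membrane level must be the
    darkest (vesicle membranes are darker than both lumen and cytoplasm).
    ``min_center_separation_nm`` defaults to one maximal vesicle diameter so
    that rings never overlap.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    pixel_size_nm: float = NATIVE_PIXEL_SIZE_NM
    n_vesicles: int = 25
    radius_range_px: tuple[int, int] = (7, 12)
    max_axis_diff_px: int = 4
    membrane_thickness_px: int = 3
    min_center_separation_nm: float | None = None
    background_level: float = 0.55
    lumen_level: float = 0.75
    membrane_level: float = 0.25
    n_distractors: int = 6
    blob_level: float = 0.40
    stripe_level: float = 0.50
    line_level: float = 0.18
    noise_sigma: float = 0.05
    contrast_factor: float = 1.0
    include_black_mask: bool = False
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.radius_range_px
        if not (7 <= lo <= hi <= 12):
            raise ValueError(f"radius_range_px must lie within [7, 12]: {self.radius_range_px}")
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.n_vesicles < 0 or self.n_distractors < 0:
            raise ValueError("object counts must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.contrast_factor <= 0:
            raise ValueError("contrast_factor must be positive")
        if not (self.membrane_level < self.lumen_level
                and self.membrane_level < self.background_level):
            raise ValueError("membrane_level must be darker than lumen and background")
        if self.min_center_separation_nm is not None and self.min_center_separation_nm <= 0:
            raise ValueError("min_center_separation_nm must be positive")

    @property
    def separation_nm(self) -> float:
        if self.min_center_separation_nm is not None:
            return self.min_center_separation_nm
        return 2.0 * self.radius_range_px[1] * self.pixel_size_nm

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class PatchDataset:
    """Labeled square patches (label 1 = contains a vesicle)."""

    patches: np.ndarray  # (n, side, side) float32 in [0, 1]
    labels: np.ndarray  # (n,) int
    side_px: int
    pixel_size_nm: float = NATIVE_PIXEL_SIZE_NM

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.patches.ndim != 3 or self.patches.shape[1:] != (self.side_px, self.side_px):
            raise ValueError("patches must have shape (n, side, side)")
        if len(self.labels) != len(self.patches):
            raise ValueError("labels/patches length mismatch")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    def subset(self, idx) -> "PatchDataset":
        return PatchDataset(self.patches[idx], self.labels[idx], self.side_px,
                            self.pixel_size_nm)

    def save(self, directory) -> None:
        """Write patches as 8-bit PNGs plus a ``labels.csv`` (patch_file,label)."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (patch, label) in enumerate(zip(self.patches, self.labels)):
            name = f"patch_{i:06d}.png"
            Image.fromarray((np.clip(patch, 0, 1) * 255).round().astype(np.uint8)).save(
                directory / name
            )
            rows.append((name, int(label)))
        pd.DataFrame(rows, columns=["patch_file", "label"]).to_csv(
            directory / "labels.csv", index=False
        )

    @classmethod
    def load(cls, directory, pixel_size_nm: float = NATIVE_PIXEL_SIZE_NM) -> "PatchDataset":
        from PIL import Image

        directory = Path(directory)
        table = pd.read_csv(directory / "labels.csv")
        patches = np.stack(
            [np.asarray(Image.open(directory / f), dtype=np.float32) / 255.0
             for f in table["patch_file"]]
        )
        return cls(patches, table["label"].to_numpy(), patches.shape[1], pixel_size_nm)


def _sample_radii(rng, config: SynthConfig) -> tuple[int, int]:
    lo, hi = config.radius_range_px
    a = int(rng.integers(lo, hi + 1))
    b_lo = max(lo, a - config.max_axis_diff_px)
    b_hi = min(hi, a + config.max_axis_diff_px)
    b = int(rng.integers(b_lo, b_hi + 1))
    return max(a, b), min(a, b)


def _point_segment_distance(px, py, x0, y0, x1, y1) -> float:
    vx, vy = x1 - x0, y1 - y0
    seg2 = vx * vx + vy * vy
    if seg2 == 0:
        return float(np.hypot(px - x0, py - y0))
    t = np.clip(((px - x0) * vx + (py - y0) * vy) / seg2, 0.0, 1.0)
    return float(np.hypot(px - (x0 + t * vx), py - (y0 + t * vy)))


def _place_mask(rng, config: SynthConfig, h: int, w: int):
    """A black exclusion rectangle anchored at a random image corner."""
    mh = int(h * rng.uniform(0.2, 0.35))
    mw = int(w * rng.uniform(0.2, 0.35))
    corner = rng.integers(0, 4)
    r0 = 0 if corner in (0, 1) else h - mh
    c0 = 0 if corner in (0, 2) else w - mw
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r0 + mh, c0 : c0 + mw] = True
    return mask, (r0, c0, r0 + mh, c0 + mw)


def generate_micrograph(config: SynthConfig) -> tuple[Micrograph, pd.DataFrame]:
    """Render one synthetic micrograph and its exact ground truth.

    Returns the image plus a DataFrame with one row per placed vesicle:
    ``x_px, y_px`` (0-based pixel coordinates, x = column), the semi-axes
    ``major_radius_px >= minor_radius_px`` and ``orientation`` ('x' if the
    major axis runs along columns).  Deterministic for a fixed config.

    Rendering order: background, vesicles (ring + lumen), distractors,
    contrast stretch about the image mean, Gaussian noise, clipping, and
    finally the optional black exclusion rectangle.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    canvas = np.full((h, w), config.background_level, dtype=np.float64)

    mask = None
    mask_box = None
    if config.include_black_mask:
        mask, mask_box = _place_mask(rng, config, h, w)

    sep_px = config.separation_nm / config.pixel_size_nm
    margin = config.radius_range_px[1] + config.membrane_thickness_px
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(f"image {h}x{w} too small for vesicles of margin {margin}")

    def clear_of_mask(y, x, extra=0.0) -> bool:
        if mask_box is None:
            return True
        r0, c0, r1, c1 = mask_box
        dy = max(r0 - y, 0, y - (r1 - 1))
        dx = max(c0 - x, 0, x - (c1 - 1))
        return float(np.hypot(dy, dx)) >= sep_px + extra

    # --- vesicles -------------------------------------------------------
    centers: list[tuple[float, float]] = []  # (y, x)
    radii: list[tuple[int, int, str]] = []
    failed = 0
    for _ in range(config.n_vesicles):
        for attempt in range(_MAX_ATTEMPTS):
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if not clear_of_mask(y, x):
                continue
            if all(np.hypot(y - cy, x - cx) >= sep_px for cy, cx in centers):
                break
        else:
            failed += 1
            continue
        major, minor = _sample_radii(rng, config)
        orientation = "x" if rng.random() < 0.5 else "y"
        centers.append((y, x))
        radii.append((major, minor, orientation))
    if failed:
        raise PlacementError(
            f"could not place {failed} of {config.n_vesicles} vesicles after "
            f"{_MAX_ATTEMPTS} attempts each; reduce n_vesicles or separation"
        )

    for (y, x), (major, minor, orientation) in zip(centers, radii):
        a, b = (major, minor) if orientation == "x" else (minor, major)
        r0 = max(int(np.floor(y)) - margin - 2, 0)
        c0 = max(int(np.floor(x)) - margin - 2, 0)
        r1 = min(int(np.ceil(y)) + margin + 3, h)
        c1 = min(int(np.ceil(x)) + margin + 3, w)
        local_shape = (r1 - r0, c1 - c0)
        center_local = (y - r0, x - c0)
        ring = ring_mask(local_shape, center_local, a, b, config.membrane_thickness_px)
        lumen = interior_mask(local_shape, center_local, a, b, config.membrane_thickness_px)
        view = canvas[r0:r1, c0:c1]
        view[lumen] = config.lumen_level
        view[ring] = config.membrane_level

    # --- distractors ----------------------------------------------------
    distractor_centers: list[tuple[float, float]] = []
    for i in range(config.n_distractors):
        kind = "blob" if i % 2 == 0 else "line"
        if kind == "blob":
            _draw_blob(rng, canvas, centers, sep_px, config, distractor_centers,
                       clear_of_mask)
        else:
            _draw_line(rng, canvas, centers, sep_px, config, distractor_centers,
                       clear_of_mask)

    # --- photometry -----------------------------------------------------
    if config.contrast_factor != 1.0:
        mean = canvas.mean()
        canvas = mean + config.contrast_factor * (canvas - mean)
    if config.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, config.noise_sigma, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    if mask is not None:
        canvas[mask] = 0.0

    truth = pd.DataFrame(
        {
            "x_px": [x for _, x in centers],
            "y_px": [y for y, _ in centers],
            "major_radius_px": [r[0] for r in radii],
            "minor_radius_px": [r[1] for r in radii],
            "orientation": [r[2] for r in radii],
        }
    )
    mg = Micrograph(
        canvas.astype(np.float32),
        config.pixel_size_nm,
        mask=mask,
        meta={
            "synthetic": True,
            "config": config,
            "distractor_centers": distractor_centers,
        },
    )
    return mg, truth


def _draw_blob(rng, canvas, vesicle_centers, sep_px, config, out_centers, clear_of_mask):
    """Mitochondria-like textured organelle: a filled dark ellipse with
    brighter internal striations (cristae)."""
    h, w = canvas.shape
    # 100-400 nm across at the configured pixel size
    diameter_px = rng.uniform(100.0, 400.0) / config.pixel_size_nm
    ra = diameter_px / 2.0
    rb = ra * rng.uniform(0.5, 0.9)
    for _ in range(_MAX_ATTEMPTS):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        if not clear_of_mask(y, x, extra=ra):
            continue
        if all(np.hypot(y - cy, x - cx) >= sep_px + ra for cy, cx in vesicle_centers):
            break
    else:
        log.warning("skipped one blob distractor: no admissible position found")
        return
    theta = rng.uniform(0, np.pi)
    r0, r1 = max(int(y - ra) - 1, 0), min(int(y + ra) + 2, h)
    c0, c1 = max(int(x - ra) - 1, 0), min(int(x + ra) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - y, xx - x
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
    stripes = np.sin(v * (2 * np.pi / rng.uniform(8.0, 14.0))) > 0
    view = canvas[r0:r1, c0:c1]
    view[inside] = config.blob_level
    view[inside & stripes] = config.stripe_level
    out_centers.append((y, x))


def _draw_line(rng, canvas, vesicle_centers, sep_px, config, out_centers, clear_of_mask):
    """Straight dark membrane, 3 px thick."""
    h, w = canvas.shape
    length = rng.uniform(80.0, 200.0)
    for _ in range(_MAX_ATTEMPTS):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        x0, y0 = x - length / 2 * np.cos(theta), y - length / 2 * np.sin(theta)
        x1, y1 = x + length / 2 * np.cos(theta), y + length / 2 * np.sin(theta)
        if not clear_of_mask(y, x, extra=length / 2):
            continue
        if all(
            _point_segment_distance(cx, cy, x0, y0, x1, y1) >= sep_px
            for cy, cx in vesicle_centers
        ):
            break
    else:
        log.warning("skipped one line distractor: no admissible position found")
        return
    r0 = max(int(min(y0, y1)) - 2, 0)
    r1 = min(int(max(y0, y1)) + 3, h)
    c0 = max(int(min(x0, x1)) - 2, 0)
    c1 = min(int(max(x0, x1)) + 3, w)
    if r1 <= r0 or c1 <= c0:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    # distance from each pixel to the segment
    vx, vy = x1 - x0, y1 - y0
    seg2 = vx * vx + vy * vy
    t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / seg2, 0.0, 1.0)
    dist = np.hypot(xx - (x0 + t * vx), yy - (y0 + t * vy))
    canvas[r0:r1, c0:c1][dist <= 1.5] = config.line_level
    out_centers.append((y, x))


def generate_patch_dataset(
    images: list[tuple[Micrograph, pd.DataFrame]],
    patch_side_px: int = 40,
    negative_ratio: float = DEFAULT_NEGATIVE_RATIO,
    include_black: bool = True,
    seed: int = 0,
    jitter_px: int = 2,
    black_fraction: float = 0.1,
    hard_negative_fraction: float = 0.35,
    edge_negative_fraction: float = 0.2,
    min_negative_distance_px: float = 13.0,
) -> PatchDataset:
    """Derive a labeled patch dataset from micrographs with ground truth.

    Positives are ``patch_side_px`` windows centered (with +-``jitter_px``
    jitter) on ground-truth vesicle centers.  Negatives are sampled at
    least one minimal vesicle diameter (``min_negative_distance_px``) from
    every vesicle center and come in three flavors: *hard* negatives
    centered just beyond that exclusion radius (an off-center vesicle is
    visible but the window is not centered on it — this is what teaches a
    sliding-window classifier to localize), *edge* negatives cut from the
    zero-padded image with centers near the border (sliding-window
    inference pads the image, so border windows are part zero — a
    classifier never shown them fires along the edges), distractor-centered
    negatives, and uniform background, plus a fraction of all-black patches
    when ``include_black`` is set (so a classifier learns the
    exclusion-mask convention).  The negative:positive count ratio equals
    ``negative_ratio`` within rounding.
    """
    if negative_ratio <= 0:
        raise ValueError("negative_ratio must be positive")
    rng = np.random.default_rng(seed)
    half = patch_side_px // 2
    positives: list[np.ndarray] = []
    skipped = 0
    per_image = []
    padded_images = []

    # positives are cut from the zero-padded image, exactly as the
    # sliding-window stages see them: a vesicle near the border yields a
    # patch that is part padding, and must still be learned as positive
    for mg, truth in images:
        h, w = mg.shape
        centers = truth[["y_px", "x_px"]].to_numpy(dtype=float)
        per_image.append((mg, centers))
        padded = np.pad(mg.pixels, half)
        padded_images.append(padded)
        for y, x in centers:
            jy = int(rng.integers(-jitter_px, jitter_px + 1))
            jx = int(rng.integers(-jitter_px, jitter_px + 1))
            s = int(round(y)) + jy  # window start in the padded frame
            t = int(round(x)) + jx
            if s < 0 or t < 0 or s + patch_side_px > h + 2 * half \
                    or t + patch_side_px > w + 2 * half:
                skipped += 1
                continue
            positives.append(padded[s : s + patch_side_px, t : t + patch_side_px])
    if skipped:
        log.info("skipped %d positive patches extending beyond image bounds", skipped)
    if not positives:
        raise ValueError("no positive patches could be extracted")

    n_pos = len(positives)
    n_neg = int(round(negative_ratio * n_pos))
    n_black = max(1, int(round(black_fraction * n_neg))) if include_black and n_neg else 0

    negatives: list[np.ndarray] = []
    # exclusion radius: one minimal vesicle diameter (~30 nm = 13 native
    # pixels).  Windows centered closer than this to a vesicle are neither
    # positives nor negatives; everything at or beyond it is fair negative
    # ground, so a sliding-window classifier learns to localize.
    min_neg_dist = float(min_negative_distance_px)

    # hard negatives: windows centered just outside the exclusion radius of
    # a vesicle, so a ring is in view but off-center
    n_hard = int(round(hard_negative_fraction * (n_neg - n_black)))
    attempts = 0
    while len(negatives) < n_hard and attempts < 100 * max(n_hard, 1):
        attempts += 1
        mg, centers = per_image[rng.integers(len(per_image))]
        if not len(centers):
            continue
        h, w = mg.shape
        cy, cx = centers[rng.integers(len(centers))]
        angle = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(min_neg_dist, min_neg_dist + 16.0)
        r0 = int(round(cy + dist * np.sin(angle))) - half
        c0 = int(round(cx + dist * np.cos(angle))) - half
        if r0 < 0 or c0 < 0 or r0 + patch_side_px > h or c0 + patch_side_px > w:
            continue
        d = np.hypot(centers[:, 0] - (r0 + half), centers[:, 1] - (c0 + half)).min()
        if d < min_neg_dist:
            continue
        negatives.append(mg.pixels[r0 : r0 + patch_side_px, c0 : c0 + patch_side_px])

    # edge negatives: windows from the zero-padded image, centered on or
    # near the border, exactly as the sliding-window stage will see them
    n_edge = int(round(edge_negative_fraction * (n_neg - n_black)))
    target = len(negatives) + n_edge
    attempts = 0
    while len(negatives) < target and attempts < 100 * max(n_edge, 1):
        attempts += 1
        pick = int(rng.integers(len(per_image)))
        mg, centers = per_image[pick]
        h, w = mg.shape
        band = int(rng.integers(0, 9))  # distance of the center to the border
        edge = int(rng.integers(4))
        if edge == 0:
            cy, cx = band, int(rng.integers(0, w))
        elif edge == 1:
            cy, cx = h - 1 - band, int(rng.integers(0, w))
        elif edge == 2:
            cy, cx = int(rng.integers(0, h)), band
        else:
            cy, cx = int(rng.integers(0, h)), w - 1 - band
        if len(centers):
            if np.hypot(centers[:, 0] - cy, centers[:, 1] - cx).min() < min_neg_dist:
                continue
        padded = padded_images[pick]
        negatives.append(padded[cy : cy + patch_side_px, cx : cx + patch_side_px])

    # distractor-centered negatives
    distractor_sites = []
    for mg, centers in per_image:
        for (y, x) in mg.meta.get("distractor_centers", []):
            distractor_sites.append((mg, centers, y, x))
    rng.shuffle(distractor_sites)
    for mg, centers, y, x in distractor_sites:
        if len(negatives) >= int(0.7 * (n_neg - n_black)):
            break
        jy, jx = rng.integers(-5, 6, size=2)
        r0 = int(round(y)) + int(jy) - half
        c0 = int(round(x)) + int(jx) - half
        h, w = mg.shape
        if r0 < 0 or c0 < 0 or r0 + patch_side_px > h or c0 + patch_side_px > w:
            continue
        if len(centers) and np.hypot(*(centers - [r0 + half, c0 + half]).T).min() < min_neg_dist:
            continue
        negatives.append(mg.pixels[r0 : r0 + patch_side_px, c0 : c0 + patch_side_px])

    # uniform background negatives
    attempts = 0
    while len(negatives) < n_neg - n_black and attempts < 100 * n_neg:
        attempts += 1
        mg, centers = per_image[rng.integers(len(per_image))]
        h, w = mg.shape
        r0 = int(rng.integers(0, h - patch_side_px + 1))
        c0 = int(rng.integers(0, w - patch_side_px + 1))
        if len(centers):
            d = np.hypot(centers[:, 0] - (r0 + half), centers[:, 1] - (c0 + half)).min()
            if d < min_neg_dist:
                continue
        negatives.append(mg.pixels[r0 : r0 + patch_side_px, c0 : c0 + patch_side_px])
    negatives.extend(
        np.zeros((patch_side_px, patch_side_px), dtype=np.float32) for _ in range(n_black)
    )

    patches = np.stack(positives + negatives).astype(np.float32)
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(len(negatives), int)])
    order = rng.permutation(len(patches))
    return PatchDataset(patches[order], labels[order], patch_side_px,
                        images[0][0].pixel_size_nm)


def write_ground_truth_csv(entries: list[tuple[str, pd.DataFrame]], path) -> None:
    """Ground-truth CSV: ``image,x_px,y_px,major_radius_px,minor_radius_px``."""
    frames = []
    for name, truth in entries:
        df = truth[["x_px", "y_px", "major_radius_px", "minor_radius_px"]].copy()
        df.insert(0, "image", name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
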