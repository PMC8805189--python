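"""Per-vesicle measurements: nearest-neighbor distance and elliptical
template area estimation.

Vesicle area is estimated by exhaustive dark-ring template matching: a bank
of axis-aligned elliptical outlines (semi-axes 7-12 px, axes differing by
at most 4 px, outline thickness 3 px) is scored against a 40x40 patch
centered on the detection; the template may shift up to 3 px in each
direction.  The score of a placement is the mean intensity under the
outline plus ``0.03 * SD`` of the four per-quadrant means (an asymmetry
penalty); the global minimum — the darkest, most symmetric ring — wins,
and the area is ``a * b * pi * pixel_area_nm2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist

from ._geometry import ring_mask
from .micrograph import NATIVE_PIXEL_SIZE_NM

__all__ = [
    "RingTemplate",
    "EllipseFit",
    "build_ring_templates",
    "score_template",
    "estimate_area",
    "nearest_neighbor_distances",
]

log = logging.getLogger(__name__)

TEMPLATE_SIDE = 40
TEMPLATE_CENTER = (20.0, 20.0)  # row, col: "21st row and 21st column", 1-based
RADIUS_MIN, RADIUS_MAX = 7, 12
MAX_AXIS_DIFF = 4
RING_THICKNESS = 3.0
SHIFT_MAX = 3
ASYMMETRY_WEIGHT = 0.03


@dataclass(frozen=True)
class RingTemplate:
    """One elliptical outline on the 40x40 grid; ``a`` runs along columns."""

    a_px: int
    b_px: int
    mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class EllipseFit:
    """Best-matching ring for one detection."""

    a_px: int
    b_px: int
    shift: tuple[int, int]  # (dx, dy)
    score: float
    area_nm2: float


def build_ring_templates() -> list[RingTemplate]:
    """All ordered (a, b) pairs with a, b in [7, 12] and |a - b| <= 4.

    Both orientations are represented (a is the column semi-axis), giving
    34 templates: 36 ordered pairs minus (7, 12) and (12, 7).
    """
    templates = []
    for a, b in product(range(RADIUS_MIN, RADIUS_MAX + 1), repeat=2):
        if abs(a - b) > MAX_AXIS_DIFF:
            continue
        mask = ring_mask((TEMPLATE_SIDE, TEMPLATE_SIDE), TEMPLATE_CENTER, a, b,
                         RING_THICKNESS)
        templates.append(RingTemplate(a, b, mask))
    return templates


def _quadrant_masks(mask: np.ndarray) -> list[np.ndarray]:
    h = TEMPLATE_SIDE // 2
    return [
        mask[:h, :h], mask[:h, h:], mask[h:, :h], mask[h:, h:],
    ]


def score_template(patch: np.ndarray, template: RingTemplate) -> float:
    """Darkness-plus-asymmetry score; lower is better.

    Mean of the patch under the ring mask plus ``0.03`` times the
    population SD of the four per-quadrant means of those same masked
    values.  A quadrant with no ring pixels is excluded from the SD.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (TEMPLATE_SIDE, TEMPLATE_SIDE):
        raise ValueError(f"patch must be {TEMPLATE_SIDE}x{TEMPLATE_SIDE}, got {patch.shape}")
    values = patch[template.mask]
    mean = values.mean()
    h = TEMPLATE_SIDE // 2
    quadrant_means = []
    for qr, qc in ((0, 0), (0, h), (h, 0), (h, h)):
        qmask = template.mask[qr : qr + h, qc : qc + h]
        if not qmask.any():
            log.debug("quadrant (%d,%d) has no ring pixels; excluded from SD", qr, qc)
            continue
        quadrant_means.append(patch[qr : qr + h, qc : qc + h][qmask].mean())
    sd = float(np.std(quadrant_means)) if len(quadrant_means) > 1 else 0.0
    return float(mean + ASYMMETRY_WEIGHT * sd)


class _TemplateBank:
    """Precomputed flat masks for vectorized scoring of all templates."""

    def __init__(self):
        self.templates = build_ring_templates()
        side2 = TEMPLATE_SIDE * TEMPLATE_SIDE
        n = len(self.templates)
        self.ring = np.zeros((n, side2), dtype=np.float64)
        self.quad = np.zeros((n, 4, side2), dtype=np.float64)
        self.quad_counts = np.zeros((n, 4), dtype=np.float64)
        h = TEMPLATE_SIDE // 2
        qsel = np.zeros((4, TEMPLATE_SIDE, TEMPLATE_SIDE), dtype=bool)
        qsel[0, :h, :h] = qsel[1, :h, h:] = qsel[2, h:, :h] = qsel[3, h:, h:] = True
        for i, t in enumerate(self.templates):
            flat = t.mask.ravel().astype(np.float64)
            self.ring[i] = flat / flat.sum()
            for q in range(4):
                sel = (t.mask & qsel[q]).ravel().astype(np.float64)
                cnt = sel.sum()
                self.quad_counts[i, q] = cnt
                if cnt:
                    self.quad[i, q] = sel / cnt
        self.areas = np.array([t.a_px * t.b_px for t in self.templates], dtype=np.float64)

    def scores(self, patch: np.ndarray) -> np.ndarray:
        flat = patch.ravel().astype(np.float64)
        means = self.ring @ flat
        qmeans = self.quad @ flat  # (n, 4)
        sds = np.empty(len(self.templates))
        for i in range(len(self.templates)):
            valid = self.quad_counts[i] > 0
            vals = qmeans[i, valid]
            sds[i] = np.std(vals) if valid.sum() > 1 else 0.0
        return means + ASYMMETRY_WEIGHT * sds


_BANK: _TemplateBank | None = None


def _bank() -> _TemplateBank:
    global _BANK
    if _BANK is None:
        _BANK = _TemplateBank()
    return _BANK


def estimate_area(
    img: np.ndarray,
    center: tuple[float, float],
    pixel_size_nm: float = NATIVE_PIXEL_SIZE_NM,
    axis_shifts_only: bool = False,
) -> EllipseFit:
    """Fit the darkest elliptical ring around ``center`` (x, y pixels).

    Exhaustive search over all 34 templates and all integer shifts with
    ``max(|dx|, |dy|) <= 3`` (or axis-aligned shifts only).  The patch is
    extracted with replicate padding so the detection sits at row 20,
    col 20 of the 40x40 window.  Ties are broken by smaller area, then
    smaller shift magnitude.  ``area_nm2 = a * b * pi * pixel_size_nm**2``.
    """
    img = np.asarray(img, dtype=np.float64)
    x, y = center
    cy, cx = int(np.floor(y + 0.5)), int(np.floor(x + 0.5))
    half = TEMPLATE_SIDE // 2
    pad = half + SHIFT_MAX
    padded = np.pad(img, pad, mode="edge")
    # in padded coordinates the unshifted patch starts at (cy + SHIFT_MAX);
    # the neighborhood additionally spans +-SHIFT_MAX rows/cols around it
    neighborhood = padded[cy : cy + TEMPLATE_SIDE + 2 * SHIFT_MAX,
                          cx : cx + TEMPLATE_SIDE + 2 * SHIFT_MAX]
    bank = _bank()
    if axis_shifts_only:
        shifts = [(0, 0)] + [
            s for d in range(1, SHIFT_MAX + 1) for s in ((d, 0), (-d, 0), (0, d), (0, -d))
        ]
    else:
        shifts = list(product(range(-SHIFT_MAX, SHIFT_MAX + 1), repeat=2))
    best = None
    for dx, dy in shifts:
        # shifting the template by (dx, dy) == sampling the patch shifted by it
        window = neighborhood[SHIFT_MAX + dy : SHIFT_MAX + dy + TEMPLATE_SIDE,
                              SHIFT_MAX + dx : SHIFT_MAX + dx + TEMPLATE_SIDE]
        scores = bank.scores(window)
        ties = np.flatnonzero(scores == scores.min())
        i = ties[np.argmin(bank.areas[ties])]
        key = (scores[i], bank.areas[i], dx * dx + dy * dy)
        if best is None or key < best[0]:
            t = bank.templates[i]
            best = (key, t.a_px, t.b_px, (dx, dy))
    _, a, b, shift = best
    area = a * b * np.pi * pixel_size_nm ** 2
    return EllipseFit(a, b, shift, float(best[0][0]), float(area))


def nearest_neighbor_distances(
    points: np.ndarray, pixel_size_nm: float
) -> np.ndarray:
    """Shortest Euclidean distance from each point to any other, in nm.

    ``points`` is (n, 2) as (x, y) pixel coordinates.  A single point has
    no neighbor and yields NaN (not zero).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(points)
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([np.nan])
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) * pixel_size_nm
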