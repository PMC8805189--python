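"""Shared elliptical-ring rasterization.

The synthetic generator and the area-estimation templates must agree on what
"an elliptical ring of thickness t" means on a pixel grid, otherwise template
matching cannot recover the generating radii exactly on noise-free images.
The convention used throughout: a pixel belongs to the outline of the
axis-aligned ellipse with semi-axes (a, b) if its radial distance from the
ellipse boundary (measured along the ray from the center) is at most t/2.
"""

from __future__ import annotations

import numpy as np

__all__ = ["radial_distance", "ring_mask", "interior_mask"]


def radial_distance(dy: np.ndarray, dx: np.ndarray, a: float, b: float) -> np.ndarray:
    """Signed distance from the ellipse boundary along the center ray.

    Negative inside the ellipse, positive outside.  ``dx`` runs along the
    semi-axis ``a`` (columns), ``dy`` along ``b`` (rows).  At the exact
    center the ray is undefined; the returned value there is ``-min(a, b)``,
    the distance to the nearest boundary point.
    """
    dy = np.asarray(dy, dtype=np.float64)
    dx = np.asarray(dx, dtype=np.float64)
    d = np.hypot(dx, dy)
    # e = d / r_boundary(theta); boundary radius along the ray is d / e.
    e = np.sqrt((dx / a) ** 2 + (dy / b) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = d * (1.0 - 1.0 / e)
    rd = np.where(d == 0, -float(min(a, b)), rd)
    return rd


def _grid(shape: tuple[int, int], center: tuple[float, float]):
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    return rows - center[0], cols - center[1]


def ring_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    thickness: float = 3.0,
) -> np.ndarray:
    """Boolean mask of the elliptical outline (band of total radial thickness)."""
    dy, dx = _grid(shape, center)
    rd = radial_distance(dy, dx, a, b)
    return np.abs(rd) <= thickness / 2.0


def interior_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    thickness: float = 3.0,
) -> np.ndarray:
    """Boolean mask of the lumen strictly inside the ring band."""
    dy, dx = _grid(shape, center)
    rd = radial_distance(dy, dx, a, b)
    return rd < -thickness / 2.0
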