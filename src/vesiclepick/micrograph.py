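"""The in-memory micrograph container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Micrograph", "NATIVE_PIXEL_SIZE_NM"]

#: Pixel size (nm) the classifiers are trained at; every input image is
#: resampled to this resolution before sliding-window inference.
NATIVE_PIXEL_SIZE_NM = 2.27


@dataclass
class Micrograph:
    """A 2D grayscale EM image with physical pixel size.

    Parameters
    ----------
    pixels:
        2D float array with intensities in [0, 1].
    pixel_size_nm:
        Physical edge length of one pixel, in nanometres.
    mask:
        Optional boolean exclusion mask (True = excluded from analysis),
        same shape as ``pixels``.
    meta:
        Free-form provenance (e.g. distractor locations for synthetic images).
    """

    pixels: np.ndarray
    pixel_size_nm: float
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"micrograph must be 2D, got shape {self.pixels.shape}")
        if self.pixel_size_nm <= 0:
            raise ValueError(f"pixel_size_nm must be positive: {self.pixel_size_nm}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match "
                    f"image shape {self.pixels.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
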