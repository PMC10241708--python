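"""Raster containers for brightfield IHC images.

An :class:`RGBImage` is an 8-bit, 3-channel transmitted-light raster with a
physical resolution (pixels per micrometre) and an optional exclusion mask
marking artifact regions (folds, fat, necrosis) that a pathologist would
strike from analysis.  The exclusion mask is the only representation of
manual slide QC in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RGBImage:
    """8-bit RGB raster with physical calibration.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array; 255 is full transmission (no stain).
    resolution_px_per_um
        Pixels per micrometre (the scanning convention here is 4 px/um).
    exclusion_mask
        Optional ``(H, W)`` boolean array; ``True`` pixels are excluded
        from all area and intensity accounting.
    """

    pixels: np.ndarray
    resolution_px_per_um: float
    exclusion_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if not self.resolution_px_per_um > 0:
            raise ValueError("resolution_px_per_um must be positive")
        if self.exclusion_mask is not None:
            self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
            if self.exclusion_mask.shape != self.pixels.shape[:2]:
                raise ValueError("exclusion mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def tissue_area_mm2(self) -> float:
        """Analyzable area in mm**2 (image minus exclusions)."""
        h, w = self.shape
        n_px = h * w
        if self.exclusion_mask is not None:
            n_px -= int(self.exclusion_mask.sum())
        um_per_px = 1.0 / self.resolution_px_per_um
        return n_px * (um_per_px**2) / 1e6


def pixel_area_mm2(n_pixels: int, resolution_px_per_um: float) -> float:
    """Convert a pixel count to mm**2 at the given resolution."""
    um_per_px = 1.0 / resolution_px_per_um
    return n_pixels * (um_per_px**2) / 1e6
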