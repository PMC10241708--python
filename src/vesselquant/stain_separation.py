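"""Optical-density conversion and color deconvolution for dual-chromogen IHC.

Brightfield chromogens obey Beer-Lambert absorption: transmitted intensity
``I = I0 * 10**(-OD)`` per channel, so ``OD = log10(I0 / I)`` is linear in
the amount of deposited chromogen.  A pixel stained by several chromogens
has an OD vector that is the amount-weighted sum of the per-stain unit
color vectors; unmixing that linear model recovers one amount map per
stain (color deconvolution).

The stain model here pairs a red endothelial chromogen (liquid permanent
red, marking CD34+ vessel walls) with a blue perivascular chromogen
(marking a-SMA+ mural cells).  The exact unit vectors depend on scanner
and chromogen lot and are configuration, not estimated from the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

I0 = 255.0
DEFAULT_I_FLOOR = 1.0
#: maximum representable OD for 8-bit input with the default intensity floor
OD_CEILING = float(np.log10(I0 / DEFAULT_I_FLOOR))

#: brightfield presets, unit-normalized below: a red chromogen absorbing
#: green/blue and a blue chromogen absorbing red/green
_DEFAULT_VECTORS = {
    "cd34": (0.214, 0.851, 0.478),
    "sma": (0.853, 0.509, 0.113),
}


class StainModelError(ValueError):
    """Degenerate stain model (collinear or rank-deficient vectors)."""


@dataclass(frozen=True)
class StainModel:
    """Named unit color vectors in OD space.

    ``vectors`` is ``(n_stains, 3)``; rows are normalized to Euclidean
    norm 1 at construction.  The matrix must have full column rank so the
    unmixing problem is well posed.
    """

    names: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise StainModelError(f"expected (n, 3) stain vectors, got {v.shape}")
        if len(self.names) != v.shape[0]:
            raise StainModelError("names/vectors length mismatch")
        if np.any(v < 0):
            raise StainModelError("stain vectors must be nonnegative in OD space")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise StainModelError("zero stain vector")
        v = v / norms[:, None]
        if np.linalg.matrix_rank(v, tol=1e-8) < v.shape[0]:
            raise StainModelError("stain vectors are collinear / rank deficient")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def n_stains(self) -> int:
        return self.vectors.shape[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float, float]]) -> "StainModel":
        return cls(tuple(d.keys()), np.array(list(d.values()), dtype=float))


def default_stain_model() -> StainModel:
    """Red (CD34) + blue (a-SMA) brightfield preset, unit-normalized."""
    return StainModel.from_dict(dict(_DEFAULT_VECTORS))


def rgb_to_od(pixels: np.ndarray, i_floor: float = DEFAULT_I_FLOOR) -> np.ndarray:
    """Per-channel optical density ``log10(255 / max(I, i_floor))``.

    Intensity 255 maps to OD 0 (no stain); intensities are floored at
    ``i_floor`` so fully opaque pixels get a finite, order-preserving OD.
    Input must be 8-bit.
    """
    pixels = np.asarray(pixels)
    if pixels.dtype != np.uint8:
        raise ValueError(f"rgb_to_od expects uint8 input, got {pixels.dtype}")
    i = np.maximum(pixels.astype(float), i_floor)
    return np.log10(I0 / i)


def mix_od(amounts: np.ndarray, stains: StainModel) -> np.ndarray:
    """Forward Beer-Lambert mixing: stain amounts ``(..., n)`` -> OD ``(..., 3)``."""
    amounts = np.asarray(amounts, dtype=float)
    return amounts @ stains.vectors


def od_to_rgb(od: np.ndarray, quantize: bool = True) -> np.ndarray:
    """Transmitted-light image from a per-channel OD map.

    With ``quantize`` the result is the 8-bit raster a scanner would
    record (round, clip); otherwise the continuous float transmittance
    scaled to [0, 255].
    """
    trans = I0 * np.power(10.0, -np.asarray(od, dtype=float))
    if not quantize:
        return trans
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stains: StainModel, method: str = "lstsq") -> np.ndarray:
    """Unmix per-pixel OD vectors into per-stain amount maps.

    ``od`` is ``(..., 3)``; returns ``(..., n_stains)`` nonnegative
    amounts.  Default is ordinary least squares with negative amounts
    clipped to zero; ``method="nnls"`` solves the constrained problem
    exactly (slower, per-pixel).
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError("OD map must have 3 channels in the last axis")
    m = stains.vectors.T  # (3, n)
    flat = od.reshape(-1, 3)
    if method == "lstsq":
        amounts, *_ = np.linalg.lstsq(m, flat.T, rcond=None)
        amounts = np.clip(amounts.T, 0.0, None)
    elif method == "nnls":
        amounts = np.empty((flat.shape[0], stains.n_stains))
        for k, row in enumerate(flat):
            amounts[k], _ = nnls(m, row)
    else:
        raise ValueError(f"unknown unmixing method {method!r}")
    return amounts.reshape(od.shape[:-1] + (stains.n_stains,))


def quantize_256(stain_od: np.ndarray, od_max: float = 2.0) -> np.ndarray:
    """Map a nonnegative OD map linearly onto the 256-grade 8-bit scale.

    ``[0, od_max]`` maps to 0..255 (nearest integer, halves to even);
    values above ``od_max`` saturate at 255.
    """
    if not od_max > 0:
        raise ValueError("od_max must be positive")
    stain_od = np.asarray(stain_od, dtype=float)
    scaled = np.clip(stain_od / od_max, 0.0, 1.0) * 255.0
    return np.rint(scaled).astype(np.uint8)


def separate_image(
    pixels: np.ndarray,
    stains: StainModel | None = None,
    i_floor: float = DEFAULT_I_FLOOR,
    method: str = "lstsq",
) -> dict[str, np.ndarray]:
    """Convenience: RGB uint8 -> per-stain OD maps keyed by stain name."""
    stains = stains or default_stain_model()
    amounts = deconvolve(rgb_to_od(pixels, i_floor=i_floor), stains, method=method)
    return {name: amounts[..., i] for i, name in enumerate(stains.names)}
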