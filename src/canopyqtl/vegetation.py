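"""Plant segmentation on the CIELAB a* channel and vegetation fraction.

Vegetation fraction (VF) is the percentage of plant pixels in a fixed
plot region of a top-down RGB image.  Plant pixels are found by
converting the image to CIELAB, keeping the a* (red-green opponent)
channel, and thresholding it with Otsu's method: green vegetation has
strongly negative a*, soil and water sit near zero or positive, so the
low-a* class is the plant class.

The sRGB -> XYZ -> CIELAB conversion is implemented here rather than
delegated so that the neutral axis maps to a* = 0 exactly: the D65
white point is taken as the image of RGB white under the RGB->XYZ
matrix, which guarantees f(X/Xn) = f(Y/Yn) for every grey pixel.
Conversions using an independently tabulated white point leave grey
pixels at |a*| of order 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "AStarImage",
    "BinaryMask",
    "VFValue",
    "rgb_to_astar",
    "otsu_threshold",
    "segment_plants",
    "compute_vf",
]

# sRGB D65 linear-RGB -> XYZ matrix (IEC 61966-2-1 primaries, high precision)
_RGB_TO_XYZ = np.array(
    [
        [0.41239080, 0.35758434, 0.18048079],
        [0.21263901, 0.71516868, 0.07219232],
        [0.01933082, 0.11919478, 0.95053215],
    ]
)
# white point := matrix image of RGB white, so grey -> a* = 0 exactly
_WHITE = _RGB_TO_XYZ @ np.ones(3)

_DELTA = 6.0 / 29.0


@dataclass
class AStarImage:
    """a* channel of a CIELAB-converted region (dimensionless)."""

    values: np.ndarray
    provenance: Optional[str] = None


@dataclass
class BinaryMask:
    """Plant/background segmentation of a region (1 = plant)."""

    values: np.ndarray
    threshold_used: float
    n_plant: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total != self.values.size:
            raise ValueError("n_total must equal the raster size")
        if self.n_plant != int(self.values.sum()):
            raise ValueError("n_plant must equal the number of 1-pixels")


@dataclass(frozen=True)
class VFValue:
    """Vegetation fraction as a percentage of plot pixels."""

    vf: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.vf <= 100.0):
            raise ValueError("vf must lie in [0, 100]")


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def rgb_to_astar(image: np.ndarray, white_point: str = "D65") -> AStarImage:
    """Convert an 8-bit sRGB image to its CIELAB a* channel.

    Pipeline: sRGB companding inverse (piecewise curve with the
    0.04045/12.92 linear segment) -> linear RGB -> XYZ (D65, 2 deg
    observer) -> CIELAB; only a* = 500 (f(X/Xn) - f(Y/Yn)) is returned.

    Parameters
    ----------
    image
        ``(H, W, 3)`` uint8 array (a single ``(3,)`` pixel also works).
    white_point
        Only the sRGB-native ``"D65"`` illuminant is supported.
    """
    if white_point != "D65":
        raise ValueError(f"unsupported white point {white_point!r}; only 'D65'")
    arr = np.asarray(image)
    if arr.shape[-1] != 3:
        raise ValueError("input must have 3 channels (RGB) on the last axis")
    lin = _srgb_to_linear(arr.astype(np.float64) / 255.0)
    xyz = lin @ _RGB_TO_XYZ.T
    fx = _lab_f(xyz[..., 0] / _WHITE[0])
    fy = _lab_f(xyz[..., 1] / _WHITE[1])
    return AStarImage(values=500.0 * (fx - fy))


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the bin index ``t`` maximizing the between-class variance
    ``w0(t) w1(t) (mu0(t) - mu1(t))**2`` of the split ``[0..t]`` vs
    ``[t+1..255]``.  Among equally optimal thresholds the midpoint of
    the optimal run is returned (rounded down), which is deterministic
    and symmetric for symmetric histograms.

    Raises
    ------
    ValueError
        If the histogram is empty or has fewer than two non-empty bins
        (a single-valued image has no Otsu threshold).
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate single-valued histogram; threshold undefined")

    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    total = w0[-1]
    s0 = np.cumsum(hist * bins)
    stotal = s0[-1]
    # candidate thresholds t = 0..254; both classes must be non-empty
    w0c = w0[:-1]
    w1c = total - w0c
    valid = (w0c > 0) & (w1c > 0)
    mu0 = np.where(w0c > 0, s0[:-1] / np.maximum(w0c, 1), 0.0)
    mu1 = np.where(w1c > 0, (stotal - s0[:-1]) / np.maximum(w1c, 1), 0.0)
    var_b = np.where(valid, w0c * w1c * (mu0 - mu1) ** 2, -np.inf)
    best = var_b.max()
    optimal = np.flatnonzero(var_b == best)
    return int((optimal[0] + optimal[-1]) // 2)


def segment_plants(
    astar: AStarImage,
    plant_side: str = "low",
    rescale: bool = True,
) -> BinaryMask:
    """Segment plant pixels from an a* image with Otsu's threshold.

    The a* values are linearly rescaled per image to the 0-255 range
    (min -> 0, max -> 255), quantized to integer bins, and Otsu's
    threshold applied; the plant class is the low-a* (green) side,
    threshold bin included.  ``plant_side="high"`` inverts the polarity
    (sanity-check use only).  ``rescale=False`` instead clips a* to
    [-128, 127] and shifts by 128, for workflows wanting a fixed domain.

    Raises
    ------
    ValueError
        If the a* image is constant (no contrast to threshold).
    """
    if plant_side not in ("low", "high"):
        raise ValueError("plant_side must be 'low' or 'high'")
    a = np.asarray(astar.values, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("a* image contains non-finite values")
    amin, amax = a.min(), a.max()
    if amax == amin:
        raise ValueError("constant a* image; segmentation undefined")
    if rescale:
        scaled = (a - amin) * (255.0 / (amax - amin))
    else:
        scaled = np.clip(a, -128.0, 127.0) + 128.0
    binned = np.rint(scaled).astype(np.int64)
    hist = np.bincount(binned.ravel(), minlength=256)
    t = otsu_threshold(hist)
    plant = binned <= t if plant_side == "low" else binned > t
    if rescale:
        thr_astar = amin + (t + 0.5) * (amax - amin) / 255.0
    else:
        thr_astar = (t + 0.5) - 128.0
    values = plant.astype(np.uint8)
    return BinaryMask(
        values=values,
        threshold_used=float(thr_astar),
        n_plant=int(values.sum()),
        n_total=int(values.size),
    )


def compute_vf(mask: BinaryMask) -> VFValue:
    """Vegetation fraction: 100 x plant pixels / total pixels."""
    if mask.n_total == 0:
        raise ValueError("empty mask raster; VF undefined")
    return VFValue(vf=100.0 * mask.n_plant / mask.n_total)
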