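"""Archery-target (AT) architecture score from merged per-plant masks.

The nine per-plant binary tiles of a plot are averaged pixel-wise into
a mean mask, which is partitioned into five concentric regions labelled
a (outermost) to e (innermost) and weighted 1 to 5 outside -> centre.
The score is

    AT = sum_i  w_i * P_i_avg / P_all_avg,      i in {a..e},

where P_i_avg is the mean mask value in region i and P_all_avg the mean
over all partition pixels.  A uniform mask gives AT = 15 (= 1+2+3+4+5)
regardless of region areas; mass concentrated near the centre raises
AT, so upright/compact plants score higher than spreading ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

__all__ = ["MeanMask", "ATRegionMap", "ATScore", "merge_tiles", "define_regions", "compute_at"]

REGION_NAMES = ("a", "b", "c", "d", "e")
#: weight per region, outside -> centre
REGION_WEIGHTS = {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5}
#: outer boundary of each region as a fraction of side/2, innermost first
_RING_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class MeanMask:
    """Pixel-wise average of nine binary plant tiles (values in [0, 1])."""

    values: np.ndarray
    side: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.side, self.side):
            raise ValueError("values must be a side x side square raster")
        if self.side % 2 != 1:
            raise ValueError("side must be odd")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("mean-mask values must lie in [0, 1]")
        self.values = v


@dataclass
class ATRegionMap:
    """Partition of a square raster into the five weighted regions.

    ``labels`` holds the weight (1..5) of each pixel's region; 0 marks
    pixels excluded from the partition (outside the largest circle in
    circular-annuli mode).
    """

    labels: np.ndarray
    shape_mode: str
    areas: Dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[0] != lab.shape[1]:
            raise ValueError("labels must be a square raster")
        if not np.isin(lab, [0, 1, 2, 3, 4, 5]).all():
            raise ValueError("labels must be in {0..5} (0 = excluded)")
        counts = {name: int((lab == w).sum()) for name, w in REGION_WEIGHTS.items()}
        empty = [name for name, n in counts.items() if n == 0]
        if empty:
            raise ValueError(f"regions {empty} are empty; side too small for 5 regions")
        self.labels = lab
        self.areas = counts

    @property
    def side(self) -> int:
        return self.labels.shape[0]

    @classmethod
    def from_labels(cls, labels: np.ndarray, shape_mode: str = "custom") -> "ATRegionMap":
        """Wrap an arbitrary 5-region label raster (e.g. an equal-area
        partition for analytic checks)."""
        return cls(labels=np.asarray(labels), shape_mode=shape_mode)


def define_regions(side: int, shape_mode: str = "square-annuli") -> ATRegionMap:
    """Partition a ``side x side`` raster into five concentric regions.

    ``square-annuli`` (default): five nested square frames whose outer
    half-widths sit at fractions {0.2, 0.4, 0.6, 0.8, 1.0} of side/2 on
    the max-norm distance from the centre pixel; frames partition the
    raster exactly.  ``circular-annuli``: the same fractions as
    Euclidean radii; pixels outside the largest circle are excluded
    from every region (label 0).  Boundary pixels belong to the inner
    region (<= comparisons); the centre pixel is always region e.

    Raises
    ------
    ValueError
        If ``side`` is even, or too small for all five regions to be
        non-empty (square-annuli needs side >= 9).
    """
    if shape_mode not in ("square-annuli", "circular-annuli"):
        raise ValueError(f"unknown shape_mode {shape_mode!r}")
    if side % 2 != 1 or side < 5:
        raise ValueError("side must be an odd integer >= 5")
    c = side // 2
    rr, cc = np.mgrid[0:side, 0:side]
    dr = np.abs(rr - c)
    dc = np.abs(cc - c)
    if shape_mode == "square-annuli":
        dist = np.maximum(dr, dc).astype(np.float64)
    else:
        dist = np.hypot(dr, dc)
    frac = dist / (side / 2.0)
    labels = np.zeros((side, side), dtype=np.int8)
    # assign outermost first so inner (<=) assignments win at boundaries
    for weight, f in zip((1, 2, 3, 4, 5), reversed(_RING_FRACTIONS)):
        labels[frac <= f] = weight
    return ATRegionMap(labels=labels, shape_mode=shape_mode)


@dataclass(frozen=True)
class ATScore:
    """AT value plus its per-region means P_a_avg .. P_e_avg."""

    at: float
    region_means: Dict[str, float]
    overall_mean: float


def merge_tiles(tiles: Sequence[np.ndarray]) -> MeanMask:
    """Average nine binary per-plant tiles pixel-wise.

    All tiles must be square with the same odd side; the result takes
    values in {0, 1/9, ..., 1}.
    """
    if len(tiles) != 9:
        raise ValueError(f"expected 9 tiles, got {len(tiles)}")
    arrs = [np.asarray(t, dtype=np.float64) for t in tiles]
    side = arrs[0].shape[0]
    for a in arrs:
        if a.shape != (side, side):
            raise ValueError("tiles must all be square with identical side")
    if side % 2 != 1:
        raise ValueError("tile side must be odd")
    mean = np.mean(arrs, axis=0)
    return MeanMask(values=mean, side=side)


def compute_at(mask: MeanMask, regions: ATRegionMap) -> ATScore:
    """Compute the archery-target score of a mean mask.

    Raises
    ------
    ValueError
        If mask and region map disagree in side, or the overall mean is
        zero (no plant signal: the score's normalizer vanishes).
    """
    if mask.side != regions.side:
        raise ValueError("mask and region map must share the same side")
    lab = regions.labels
    vals = mask.values
    in_part = lab > 0
    overall = float(vals[in_part].mean())
    if overall == 0.0:
        raise ValueError("empty mask (overall mean 0); AT undefined")
    region_means = {
        name: float(vals[lab == w].mean()) for name, w in REGION_WEIGHTS.items()
    }
    at = sum(REGION_WEIGHTS[n] * region_means[n] for n in REGION_NAMES) / overall
    return ATScore(at=float(at), region_means=region_means, overall_mean=overall)
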