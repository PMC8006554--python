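"""Plot-layout geometry and region/tile extraction.

A field raster (orthomosaic, already rotated and resampled upstream so
that image axes align with the planting grid) is described by a
:class:`PlotLayout`: a grid of fixed-size plot rectangles, each covering
a 3 x 3 sub-grid of plants of one line.  At the default 2 mm/pixel
resolution a plot region is 450 x 270 pixels (900 x 540 mm).  Field rows
(30 cm apart) run along the image width, so the three row positions are
``row_spacing_px`` = 150 px apart horizontally; plants within a row
(18 cm apart) are ``plant_spacing_px`` = 90 px apart vertically.

All rectangles use 0-based, half-open pixel indexing
``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = ["PlotLayout", "PlotRegion", "extract_plot_region", "extract_plant_tiles"]


@dataclass(frozen=True)
class PlotLayout:
    """Geometry of plot rectangles and plant centres on a field raster.

    Parameters
    ----------
    origin
        (row, col) pixel of the top-left corner of the plot grid.
    plot_width_px, plot_height_px
        Plot rectangle size in pixels.  Defaults 450 x 270.
    plant_spacing_px
        Spacing of plants within a field row (vertical image axis);
        default 90 px = 18 cm at 2 mm/px.
    row_spacing_px
        Spacing between field rows (horizontal image axis); default
        150 px = 30 cm at 2 mm/px.
    grid
        Mapping ``plot_id -> (grid_row, grid_col)`` placing each plot's
        rectangle at ``origin + (grid_row * plot_height_px,
        grid_col * plot_width_px)``.
    resolution_mm_per_px
        Ground sampling distance; default 2 mm/pixel.
    """

    origin: Tuple[int, int] = (0, 0)
    plot_width_px: int = 450
    plot_height_px: int = 270
    plant_spacing_px: int = 90
    row_spacing_px: int = 150
    grid: Dict[str, Tuple[int, int]] = field(default_factory=lambda: {"plot0": (0, 0)})
    resolution_mm_per_px: float = 2.0

    def __post_init__(self) -> None:
        if self.plot_width_px <= 0 or self.plot_height_px <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.plant_spacing_px <= 0 or self.row_spacing_px <= 0:
            raise ValueError("plant and row spacings must be positive")
        # all 9 plant centres must lie strictly inside the plot rectangle
        for r, c in self.plant_centres_local():
            if not (0 < r < self.plot_height_px - 1 and 0 < c < self.plot_width_px - 1):
                raise ValueError(
                    "plant centres fall outside the plot rectangle; "
                    "decrease spacings or enlarge the plot"
                )

    @classmethod
    def from_field_units(
        cls,
        plant_spacing_mm: float = 180.0,
        row_spacing_mm: float = 300.0,
        resolution_mm_per_px: float = 2.0,
        **kwargs,
    ) -> "PlotLayout":
        """Build a layout from field distances (mm) and a resolution."""
        return cls(
            plant_spacing_px=int(round(plant_spacing_mm / resolution_mm_per_px)),
            row_spacing_px=int(round(row_spacing_mm / resolution_mm_per_px)),
            resolution_mm_per_px=resolution_mm_per_px,
            **kwargs,
        )

    @classmethod
    def grid_of(cls, plot_ids: List[str], n_cols: int, **kwargs) -> "PlotLayout":
        """Lay out ``plot_ids`` row-major on a grid ``n_cols`` plots wide."""
        grid = {pid: divmod(i, n_cols) for i, pid in enumerate(plot_ids)}
        return cls(grid=grid, **kwargs)

    def plant_centres_local(self) -> List[Tuple[int, int]]:
        """The 9 plant centres (row, col) relative to a plot rectangle,
        in row-major order."""
        cy = self.plot_height_px // 2
        cx = self.plot_width_px // 2
        return [
            (cy + dr * self.plant_spacing_px, cx + dc * self.row_spacing_px)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        ]

    def plot_rectangle(self, plot_id: str) -> Tuple[int, int, int, int]:
        """Half-open rectangle ``(r0, r1, c0, c1)`` of a plot on the raster."""
        if plot_id not in self.grid:
            raise KeyError(f"unknown plot_id {plot_id!r}")
        gr, gc = self.grid[plot_id]
        r0 = self.origin[0] + gr * self.plot_height_px
        c0 = self.origin[1] + gc * self.plot_width_px
        return r0, r0 + self.plot_height_px, c0, c0 + self.plot_width_px

    def raster_shape(self) -> Tuple[int, int]:
        """Smallest (height, width) raster holding every plot rectangle."""
        r1 = max(self.plot_rectangle(pid)[1] for pid in self.grid)
        c1 = max(self.plot_rectangle(pid)[3] for pid in self.grid)
        return r1, c1

    def default_tile_side(self) -> int:
        """Largest odd tile side that keeps the nine per-plant tiles
        disjoint: ``<= min(plant_spacing_px, row_spacing_px) - 1``."""
        side = min(self.plant_spacing_px, self.row_spacing_px) - 1
        return side if side % 2 == 1 else side - 1


@dataclass
class PlotRegion:
    """One plot's RGB crop plus its 9 plant centres (region coordinates)."""

    plot_id: str
    image: np.ndarray
    plant_centres: List[Tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.plant_centres) != 9:
            raise ValueError("a plot region has exactly 9 plant centres")


def extract_plot_region(raster: np.ndarray, layout: PlotLayout, plot_id: str) -> PlotRegion:
    """Crop one plot rectangle out of a field raster.

    No resampling is performed; the crop is a copy of the raster pixels
    in the half-open rectangle declared by the layout.

    Raises
    ------
    KeyError
        If ``plot_id`` is not in the layout grid.
    ValueError
        If the rectangle is not fully inside the raster.
    """
    raster = np.asarray(raster)
    if raster.ndim < 2:
        raise ValueError("raster must be at least 2-D")
    r0, r1, c0, c1 = layout.plot_rectangle(plot_id)
    if r0 < 0 or c0 < 0 or r1 > raster.shape[0] or c1 > raster.shape[1]:
        raise ValueError(
            f"plot {plot_id!r} rectangle [{r0}:{r1}, {c0}:{c1}] exceeds "
            f"raster bounds {raster.shape[:2]}"
        )
    return PlotRegion(
        plot_id=plot_id,
        image=raster[r0:r1, c0:c1].copy(),
        plant_centres=layout.plant_centres_local(),
    )


def extract_plant_tiles(region: PlotRegion, tile_side_px: int) -> List[np.ndarray]:
    """Cut nine square tiles centred on the plant centres.

    Tiles are returned in row-major plant order.  ``tile_side_px`` must
    be odd so each tile has a unique centre pixel, and every tile must
    fit inside the region.
    """
    if tile_side_px % 2 != 1 or tile_side_px < 1:
        raise ValueError("tile_side_px must be a positive odd integer")
    half = tile_side_px // 2
    h, w = region.image.shape[:2]
    tiles = []
    for r, c in region.plant_centres:
        r0, c0 = r - half, c - half
        r1, c1 = r + half + 1, c + half + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(
                f"tile of side {tile_side_px} around plant centre ({r}, {c}) "
                f"overruns the region; use a smaller tile_side_px"
            )
        tiles.append(region.image[r0:r1, c0:c1].copy())
    return tiles
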