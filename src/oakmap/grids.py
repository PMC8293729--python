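"""Raster grid geometry.

Everything in the package lives on a single north-up, square-pixel grid:
rasters are plain 2-D numpy arrays indexed ``[row, col]`` with row 0 at the
northern edge. A 50 m pixel is 0.25 ha, the resolution of the biophysical
layers the analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions in pixels; must be >= 1.
    pixel_size:
        Pixel edge length in map units (metres). Default 50.
    origin:
        Map coordinates ``(x, y)`` of the lower-left corner of the grid.
    region_count:
        Number of administrative regions the landscape is divided into.
    crs:
        Free-text coordinate-reference tag carried through outputs; the
        package performs no reprojection.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 50.0
    origin: tuple[float, float] = (0.0, 0.0)
    region_count: int = 3
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.region_count < 1:
            raise ValueError("region_count must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares (50 m -> 0.25 ha)."""
        return self.pixel_size**2 / 10_000.0

    @property
    def area_ha(self) -> float:
        return self.n_pixels * self.pixel_area_ha

    def cell_centers(
        self, rows: np.ndarray, cols: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of pixel centres for ``rows``/``cols`` index arrays."""
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x0, y0 = self.origin
        x = x0 + (cols + 0.5) * self.pixel_size
        # row 0 is the northern (top) edge
        y = y0 + (self.n_rows - rows - 0.5) * self.pixel_size
        return x, y

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        return (rows >= 0) & (rows < self.n_rows) & (cols >= 0) & (cols < self.n_cols)
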