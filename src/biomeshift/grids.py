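"""Geographic grid descriptor shared by every raster layer in a run.

All layers are geographic (lon/lat), pixel-centre registered, stored
north-up (row 0 is the northernmost row). Mixing grids is a hard error:
every operation that combines layers calls :func:`check_same_grid`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridDescriptor", "GridMismatchError", "check_same_grid"]


class GridMismatchError(ValueError):
    """Raised when two layers do not share an identical grid."""


@dataclass(frozen=True)
class GridDescriptor:
    """Regular lon/lat grid, square pixels, pixel-centre registration.

    Parameters
    ----------
    rows, cols
        Grid shape; rows run north to south.
    origin_lon, origin_lat
        West and north *edges* of the grid (corner of the top-left pixel).
    pixel_size
        Pixel edge length in degrees.
    """

    rows: int
    cols: int
    origin_lon: float = -75.0
    origin_lat: float = 5.0
    pixel_size: float = 0.05

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError(f"degenerate grid {self.rows}x{self.cols}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def lons(self) -> np.ndarray:
        """Pixel-centre longitudes, west to east."""
        return self.origin_lon + (np.arange(self.cols) + 0.5) * self.pixel_size

    def lats(self) -> np.ndarray:
        """Pixel-centre latitudes, north to south (decreasing)."""
        return self.origin_lat - (np.arange(self.rows) + 0.5) * self.pixel_size

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) pixel-centre arrays of shape (rows, cols)."""
        lon, lat = np.meshgrid(self.lons(), self.lats())
        return lon, lat

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Flat cell index for coordinates; -1 where outside the grid."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.pixel_size)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.pixel_size)
        inside = (col >= 0) & (col < self.cols) & (row >= 0) & (row < self.rows)
        idx = np.where(inside, row * self.cols + col, -1)
        return idx.astype(np.int64)


def check_same_grid(*grids: GridDescriptor) -> GridDescriptor:
    """Assert all descriptors are identical; return the common one."""
    ref = grids[0]
    for g in grids[1:]:
        if g != ref:
            raise GridMismatchError(f"grid mismatch: {g} vs {ref}")
    return ref
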