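"""3-D density-map container with physical-frame value lookup.

Grids are stored internally in canonical ZYX axis order; physical positions
(Å) map to fractional grid indices through the voxel size and the origin
(the physical position of grid index (0, 0, 0)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["DensityMap", "MapStats"]


@dataclass
class MapStats:
    minimum: float
    maximum: float
    mean: float
    rms: float


@dataclass
class DensityMap:
    """Scalar 3-D grid in ZYX order with voxel size and origin in Å.

    ``origin_rule`` records which MRC header convention produced the origin
    ("origin-field", "start-indices" or "synthetic").
    """

    grid: np.ndarray  # (nz, ny, nx)
    voxel_size: np.ndarray  # (3,) Å, xyz order
    origin: np.ndarray  # (3,) Å, xyz order
    origin_rule: str = "synthetic"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3-D array")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.grid.shape
        return nx, ny, nz

    @property
    def stats(self) -> MapStats:
        g = self.grid
        return MapStats(float(g.min()), float(g.max()), float(g.mean()),
                        float(g.std()))

    def physical_to_index(self, positions: np.ndarray) -> np.ndarray:
        """Fractional xyz grid indices for physical positions (N, 3)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        return (pos - self.origin) / self.voxel_size

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """True where a physical position lies inside the grid's box."""
        idx = self.physical_to_index(positions)
        nx, ny, nz = self.shape_xyz
        upper = np.array([nx, ny, nz], dtype=float) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    def values_at(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear interpolation at physical positions.

        Returns ``(values, inside)``; positions outside the grid bounding box
        get value ``-inf`` and ``inside`` False (the side channel the
        coverage counters consume).
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        idx = self.physical_to_index(pos)
        inside = self.contains(pos)
        # map_coordinates wants index order matching the array: z, y, x
        coords = idx[:, ::-1].T
        vals = map_coordinates(self.grid, coords, order=1, mode="nearest")
        vals = np.where(inside, vals, -np.inf)
        return vals, inside

    def with_grid(self, grid: np.ndarray) -> "DensityMap":
        return DensityMap(grid=grid, voxel_size=self.voxel_size.copy(),
                          origin=self.origin.copy(),
                          origin_rule=self.origin_rule)
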