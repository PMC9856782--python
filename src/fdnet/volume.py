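"""Binary voxel volumes — the objects box counting runs on."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3D binary occupancy grid.

    ``grid`` is strictly boolean (a voxel is filled or empty); any input that
    is not already 0/1-valued is rejected rather than silently binarized.
    ``voxel_size_mm`` is carried as metadata only — box counting is purely
    grid-based.
    """

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError("voxel grid must be 3-dimensional")
        if any(s < 1 for s in grid.shape):
            raise ValueError("all three extents must be >= 1")
        if grid.dtype != bool:
            vals = np.unique(grid)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("occupancy must be strictly binary")
            grid = grid.astype(bool)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        self.grid = grid

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_filled(self) -> int:
        return int(self.grid.sum())
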