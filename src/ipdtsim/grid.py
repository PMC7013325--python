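"""Voxel grid geometry shared by all spatial fields.

Convention: 0-based voxel indices; voxel (i, j, k) occupies the half-open
box ``[origin + i*spacing, origin + (i+1)*spacing)``; all world coordinates
are in cm.  Spacings are stored per axis and never assumed cubic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel lattice.

    Parameters
    ----------
    dims
        Number of voxels per axis (nx, ny, nz); each >= 1.
    spacing
        Physical voxel edge length per axis in cm; each > 0.
    origin
        World coordinate (cm) of the corner of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("dims, spacing and origin must be length-3")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must be >= 1 per axis, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be > 0 per axis, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3 (product of per-axis spacings)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the whole grid, cm."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (cm) of voxel centers along one axis."""
        n = self.dims[axis]
        s = self.spacing[axis]
        o = self.origin[axis]
        return o + (np.arange(n) + 0.5) * s

    def world_to_index(self, point) -> tuple[int, int, int]:
        """Voxel index containing a world point (may lie outside the grid)."""
        p = np.asarray(point, dtype=float)
        return tuple(
            int(np.floor((p[a] - self.origin[a]) / self.spacing[a])) for a in range(3)
        )

    def contains_index(self, idx) -> bool:
        return all(0 <= idx[a] < self.dims[a] for a in range(3))
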