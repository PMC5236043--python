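"""Voxel grids and activity images.

Conventions used throughout the package:

* array axis order is ``(x, y, z)`` with z the scanner (axial) axis — the
  slice axis for the 2D projector;
* ``origin`` is the physical position (mm) of the *center* of voxel
  ``(0, 0, 0)``; all coordinates refer to voxel centers; indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ActivityImage", "GeometryError"]


class GeometryError(ValueError):
    """Raised when an object does not fit the voxel grid."""


@dataclass(frozen=True)
class VoxelGrid:
    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing and origin must have length 3")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def lower_edge(self, axis: int) -> float:
        return self.origin[axis] - 0.5 * self.spacing[axis]

    def upper_edge(self, axis: int) -> float:
        return (
            self.origin[axis]
            + (self.dims[axis] - 0.5) * self.spacing[axis]
        )

    def contains_point(self, point) -> bool:
        """True if ``point`` (mm) lies within the grid's outer voxel edges."""
        return all(
            self.lower_edge(a) <= point[a] <= self.upper_edge(a) for a in range(3)
        )

    def contains_sphere(self, center, radius: float) -> bool:
        return all(
            self.lower_edge(a) <= center[a] - radius
            and center[a] + radius <= self.upper_edge(a)
            for a in range(3)
        )

    def nearest_index(self, point) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to ``point`` (mm)."""
        idx = []
        for a in range(3):
            i = int(round((point[a] - self.origin[a]) / self.spacing[a]))
            idx.append(min(max(i, 0), self.dims[a] - 1))
        return tuple(idx)

    def index_center(self, index) -> tuple[float, float, float]:
        return tuple(
            self.origin[a] + self.spacing[a] * index[a] for a in range(3)
        )

    def meshgrid(self):
        """Voxel-center coordinate arrays (broadcastable, mm)."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z


@dataclass
class ActivityImage:
    """A 3D activity-concentration map for one time frame.

    ``values`` are Bq/mL on ``grid`` (reconstructed images share the type;
    their absolute scale is arbitrary, which is harmless because every
    reported quantity is a same-image ratio). ``frame_start`` and
    ``frame_duration`` are minutes.
    """

    grid: VoxelGrid
    values: np.ndarray
    frame_start: float = 0.0
    frame_duration: float = 10.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        if np.any(self.values < 0):
            raise ValueError("activity values must be >= 0")

    @property
    def total_activity(self) -> float:
        """Total activity in Bq (concentration × voxel volume in mL)."""
        return float(self.values.sum() * self.grid.voxel_volume_ml)

    def copy_with(self, values: np.ndarray) -> "ActivityImage":
        return ActivityImage(
            grid=self.grid,
            values=values,
            frame_start=self.frame_start,
            frame_duration=self.frame_duration,
            meta=dict(self.meta),
        )
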