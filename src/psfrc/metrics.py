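"""VOI definitions, quantification metrics and recovery coefficients.

Three clinically used per-lesion metrics are computed inside a
sphere-shaped VOI of the same diameter as the physical sphere:

* ``A_max`` — maximum voxel value;
* ``A_50bg`` — mean of voxels at or above the background-corrected 50%
  isocontour threshold ``T = bg + 0.5·(A_max − bg)`` (the EARL-style
  convention; the isocontour support is restricted to the sphere VOI);
* ``A_avg`` — mean over the whole VOI.

Recovery coefficients divide each metric by the true sphere concentration,
which is either read off the image from the large reference VOI
("measured" truth, the default, mirroring how a physical scan is analyzed)
or taken from the analytic phantom decay curve ("oracle" truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ActivityImage, GeometryError, VoxelGrid
from .phantom import BoxRegion, PhantomSpec

__all__ = [
    "VOIMask",
    "MetricSet",
    "RCRecord",
    "sphere_voi",
    "box_voi",
    "measure_max",
    "measure_a50bg",
    "measure_avg",
    "measure_set",
    "measure_reference",
    "measure_background",
    "compute_rc",
]


@dataclass(frozen=True)
class VOIMask:
    """A set of voxel indices on a grid, with the nominal volume it stands
    for (which generally differs from the voxelized volume)."""

    grid: VoxelGrid
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    nominal_volume_ml: float

    def __post_init__(self) -> None:
        if self.indices[0].size == 0:
            raise ValueError("VOI must be non-empty")

    @property
    def n_voxels(self) -> int:
        return int(self.indices[0].size)

    @property
    def voxel_volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_ml

    def values(self, img: ActivityImage) -> np.ndarray:
        if img.grid.dims != self.grid.dims:
            raise ValueError("image grid does not match VOI grid")
        return img.values[self.indices]


def sphere_voi(grid: VoxelGrid, center, diameter: float) -> VOIMask:
    """Sphere-shaped VOI: voxels whose centers lie strictly inside the
    sphere (distance < radius); falls back to the single nearest voxel when
    no center qualifies (sub-voxel spheres).

    Note the boundary case of a 4-mm sphere on a 2-mm grid: the radius
    exactly equals the grid pitch, so the strict inequality excludes the
    six face neighbors and the VOI is a single voxel, same as for 3 mm.
    """
    if not grid.contains_point(center):
        raise GeometryError(f"VOI center {center} outside grid")
    r = 0.5 * diameter
    x, y, z = grid.meshgrid()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    inside = d2 < r * r
    if not inside.any():
        inside[grid.nearest_index(center)] = True
    idx = np.nonzero(inside)
    vol_ml = (4.0 / 3.0) * np.pi * r**3 / 1000.0
    return VOIMask(grid=grid, indices=idx, nominal_volume_ml=vol_ml)


def box_voi(grid: VoxelGrid, region: BoxRegion) -> VOIMask:
    mask = region.mask(grid)
    return VOIMask(
        grid=grid, indices=np.nonzero(mask), nominal_volume_ml=region.volume_ml
    )


def measure_max(img: ActivityImage, voi: VOIMask) -> float:
    return float(voi.values(img).max())


def measure_a50bg(img: ActivityImage, voi: VOIMask, background: float) -> float:
    """Background-corrected 50%-of-max isocontour mean.

    Threshold ``T = background + 0.5·(A_max − background)`` with A_max taken
    inside the VOI; returns the mean over VOI voxels with value ≥ T. If
    A_max ≤ background (cold/degenerate case) returns A_max.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    vals = voi.values(img)
    a_max = float(vals.max())
    if a_max <= background:
        return a_max
    threshold = background + 0.5 * (a_max - background)
    return float(vals[vals >= threshold].mean())


def measure_avg(img: ActivityImage, voi: VOIMask) -> float:
    return float(voi.values(img).mean())


@dataclass(frozen=True)
class MetricSet:
    a_max: float
    a_50bg: float
    a_avg: float

    def __post_init__(self) -> None:
        if self.a_avg > self.a_max + 1e-12 or self.a_50bg > self.a_max + 1e-12:
            raise ValueError("A_avg and A_50bg cannot exceed A_max")


def measure_set(img: ActivityImage, voi: VOIMask, background: float) -> MetricSet:
    return MetricSet(
        a_max=measure_max(img, voi),
        a_50bg=measure_a50bg(img, voi, background),
        a_avg=measure_avg(img, voi),
    )


def measure_reference(img: ActivityImage, phantom: PhantomSpec) -> float:
    """Mean over the 6-mL reference VOI — the measured true sphere
    concentration."""
    return measure_avg(img, box_voi(img.grid, phantom.reference_voi))


def measure_background(img: ActivityImage, phantom: PhantomSpec) -> float:
    """Mean over the 15-mL background VOI."""
    return measure_avg(img, box_voi(img.grid, phantom.background_voi))


@dataclass(frozen=True)
class RCRecord:
    """Recovery coefficients of one sphere in one frame/reconstruction."""

    sphere_id: int
    diameter: float
    frame_index: int
    true_ratio: float
    rc_max: float
    rc_50bg: float
    rc_avg: float
    recon_label: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        for rc in (self.rc_max, self.rc_50bg, self.rc_avg):
            if not np.isfinite(rc) or rc < 0:
                raise ValueError(f"RCs must be finite and >= 0, got {rc}")


def compute_rc(metrics: MetricSet, true_concentration: float) -> dict[str, float]:
    """Metric → recovery coefficient: each A divided by the true
    concentration. Scale-invariant: scaling image and truth together by any
    k > 0 leaves RCs unchanged."""
    if not true_concentration > 0:
        raise ValueError("true_concentration must be > 0")
    return {
        "rc_max": metrics.a_max / true_concentration,
        "rc_50bg": metrics.a_50bg / true_concentration,
        "rc_avg": metrics.a_avg / true_concentration,
    }
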