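"""Digital wall-less multi-sphere phantom.

The phantom emulates a physical dual-isotope contrast-sweep setup: twelve
small gel spheres of uniform F-18 concentration (diameters 3–12 mm) strung
along a line, embedded directly in a C-11 loaded background medium with no
inactive wall between sphere and background, plus a large F-18 reference
source. Because C-11 decays ~5.4× faster than F-18, the true
sphere-to-background concentration ratio rises from its initial ~1:1 to
~15:1 within about 100 minutes, sweeping the clinically relevant contrast
range within a single acquisition.

Two fixed measurement regions mirror the analysis protocol: a nominal 6-mL
box VOI inside the reference source (reads the true sphere concentration)
and a nominal 15-mL box VOI inside the background medium (reads background
concentration). Both are large enough to be immune to resolution artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .decay import C11, F18, Isotope, frame_mean_concentration
from .grid import ActivityImage, GeometryError, VoxelGrid

__all__ = [
    "SphereSpec",
    "BoxRegion",
    "BackgroundSpec",
    "PhantomSpec",
    "FULL_SPHERE_DIAMETERS_MM",
    "STUDY_DIAMETERS_MM",
    "build_phantom",
    "default_phantom",
    "study_phantom",
    "true_ratio",
    "rasterize",
    "near_cubic_dims",
]

#: Sphere diameters (mm) of the full twelve-sphere set, in string order.
FULL_SPHERE_DIAMETERS_MM = (10, 10, 6, 6, 12, 4, 10, 3, 8, 4, 4, 6)

#: One sphere per unique diameter — the reduced set the experiments sweep.
STUDY_DIAMETERS_MM = (12, 10, 8, 6, 4, 3)


@dataclass(frozen=True)
class SphereSpec:
    """One hot sphere: diameter (mm), center (mm), concentration at t=0."""

    diameter: float
    center: tuple[float, float, float]
    concentration0: float
    isotope: Isotope = F18

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if self.concentration0 < 0:
            raise ValueError("concentration0 must be >= 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def volume_ml(self) -> float:
        return (4.0 / 3.0) * np.pi * self.radius**3 / 1000.0


@dataclass(frozen=True)
class BoxRegion:
    """Axis-aligned box given by center (mm) and edge lengths (mm)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "size", tuple(float(s) for s in self.size))
        if any(s <= 0 for s in self.size):
            raise ValueError(f"box size must be > 0, got {self.size}")

    @property
    def volume_ml(self) -> float:
        return float(np.prod(self.size)) / 1000.0

    def index_slices(self, grid: VoxelGrid) -> tuple[slice, slice, slice]:
        """Voxel-index slices of the voxels whose centers lie in the box.

        Counts are made deterministic by rounding the box to whole voxels:
        ``n = round(size / spacing)`` voxels per axis, centered on the box
        center.
        """
        slices = []
        for a in range(3):
            n = int(round(self.size[a] / grid.spacing[a]))
            n = max(n, 1)
            c = (self.center[a] - grid.origin[a]) / grid.spacing[a]
            first = int(round(c - (n - 1) / 2.0))
            last = first + n
            if first < 0 or last > grid.dims[a]:
                raise GeometryError(
                    f"box {self} exceeds grid along axis {a}: [{first}, {last})"
                )
            slices.append(slice(first, last))
        return tuple(slices)

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        m = np.zeros(grid.dims, dtype=bool)
        m[self.index_slices(grid)] = True
        return m

    def contains_point(self, point) -> bool:
        return all(
            abs(point[a] - self.center[a]) <= 0.5 * self.size[a] for a in range(3)
        )

    def min_distance_to_point(self, point) -> float:
        d = np.array(
            [
                max(abs(point[a] - self.center[a]) - 0.5 * self.size[a], 0.0)
                for a in range(3)
            ]
        )
        return float(np.linalg.norm(d))


@dataclass(frozen=True)
class BackgroundSpec:
    region: BoxRegion
    concentration0: float
    isotope: Isotope = C11

    def __post_init__(self) -> None:
        if self.concentration0 < 0:
            raise ValueError("concentration0 must be >= 0")


def near_cubic_dims(n_voxels: int) -> tuple[int, int, int]:
    """Most cube-like integer factor triple of ``n_voxels`` (ascending).

    Used to realize nominal-volume "cube" VOIs with an exact voxel count on
    a given grid (e.g. 6 mL at 2 mm isotropic → 750 voxels → 5×10×15).
    Minimizes the max/min side ratio; ties broken lexicographically.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    best = None
    for a in range(1, int(round(n_voxels ** (1 / 3))) + 1):
        if n_voxels % a:
            continue
        m = n_voxels // a
        for b in range(a, int(np.sqrt(m)) + 1):
            if m % b:
                continue
            c = m // b
            triple = (a, b, c)
            key = (c / a, triple)
            if best is None or key < best[0]:
                best = (key, triple)
    assert best is not None
    return best[1]


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom: spheres + background + reference source + fixed VOIs.

    ``reference_source`` is the physical slab of sphere-concentration tracer
    that hosts the 6-mL ``reference_voi``; ``background_voi`` is the 15-mL
    box inside the background medium.
    """

    spheres: tuple[SphereSpec, ...]
    background: BackgroundSpec
    reference_source: BoxRegion
    reference_voi: BoxRegion
    background_voi: BoxRegion

    def __post_init__(self) -> None:
        object.__setattr__(self, "spheres", tuple(self.spheres))
        for i, a in enumerate(self.spheres):
            for b in self.spheres[i + 1 :]:
                d = np.linalg.norm(np.subtract(a.center, b.center))
                if d <= a.radius + b.radius:
                    raise ValueError(
                        f"spheres at {a.center} and {b.center} overlap"
                    )
        for voi in (self.reference_voi, self.background_voi):
            for s in self.spheres:
                if voi.min_distance_to_point(s.center) <= s.radius:
                    raise ValueError("measurement VOI intersects a sphere")

    @property
    def sphere_isotope(self) -> Isotope:
        isos = {s.isotope.name for s in self.spheres}
        if len(isos) != 1:
            raise ValueError("spheres must share one isotope")
        return self.spheres[0].isotope

    @property
    def sphere_concentration0(self) -> float:
        concs = {s.concentration0 for s in self.spheres}
        if len(concs) != 1:
            raise ValueError("spheres must share one concentration")
        return self.spheres[0].concentration0

    @property
    def diameters(self) -> tuple[float, ...]:
        return tuple(s.diameter for s in self.spheres)

    def with_sphere_offset(self, offset_mm) -> "PhantomSpec":
        """Shift all sphere centers by ``offset_mm`` (robustness studies)."""
        spheres = tuple(
            replace(s, center=tuple(np.add(s.center, offset_mm))) for s in self.spheres
        )
        return replace(self, spheres=spheres)


def with_unit_frame_contrast(
    phantom: PhantomSpec, frame_start: float = 0.0, frame_duration: float = 10.0
) -> PhantomSpec:
    """Variant whose *frame-averaged* ratio is exactly 1 for one frame.

    With equal t=0 concentrations, the faster background decay already
    lifts the first 10-minute frame's average ratio to ~1.14. Raising the
    background start concentration by that factor makes the given frame a
    true unit-contrast measurement (the instantaneous ratio crosses 1
    during the frame), which is the clean setting for spill-in/spill-out
    cancellation checks.
    """
    fm_s = frame_mean_concentration(
        1.0, phantom.sphere_isotope, frame_start, frame_duration
    )
    fm_b = frame_mean_concentration(
        1.0, phantom.background.isotope, frame_start, frame_duration
    )
    bg = BackgroundSpec(
        region=phantom.background.region,
        concentration0=phantom.sphere_concentration0 * fm_s / fm_b,
        isotope=phantom.background.isotope,
    )
    return replace(phantom, background=bg)


def true_ratio(
    phantom: PhantomSpec, frame_start: float, frame_duration: float
) -> float:
    """True sphere-to-background concentration ratio for one frame.

    Ratio of frame-averaged sphere concentration to frame-averaged
    background concentration. Being a same-time ratio it is independent of
    any decay-correction convention, and it increases frame over frame
    whenever the sphere half-life exceeds the background half-life.
    """
    cs = frame_mean_concentration(
        phantom.sphere_concentration0,
        phantom.sphere_isotope,
        frame_start,
        frame_duration,
    )
    cb = frame_mean_concentration(
        phantom.background.concentration0,
        phantom.background.isotope,
        frame_start,
        frame_duration,
    )
    if cb == 0:
        raise ZeroDivisionError("background frame-mean concentration is zero")
    return cs / cb


def rasterize(
    phantom: PhantomSpec,
    grid: VoxelGrid,
    frame_start: float,
    frame_duration: float,
    supersample: int = 4,
) -> ActivityImage:
    """Paint the frame-averaged phantom onto a voxel grid.

    Each voxel overlapping a sphere gets a volume-weighted mix of sphere and
    background concentration, estimated by subdividing the voxel into
    ``supersample``³ sub-voxels and testing sub-voxel centers against the
    sphere surface — the wall-less design: sphere and background meet with
    no inactive gap. ``supersample=1`` reduces to voxel-center in/out
    rasterization.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    for s in phantom.spheres:
        if not grid.contains_sphere(s.center, s.radius):
            raise GeometryError(f"sphere at {s.center} (d={s.diameter}) outside grid")

    cb = frame_mean_concentration(
        phantom.background.concentration0,
        phantom.background.isotope,
        frame_start,
        frame_duration,
    )
    cref = frame_mean_concentration(
        phantom.sphere_concentration0,
        phantom.sphere_isotope,
        frame_start,
        frame_duration,
    )

    values = np.zeros(grid.dims)
    values[phantom.background.region.index_slices(grid)] = cb
    values[phantom.reference_source.index_slices(grid)] = cref

    # sub-voxel center offsets in voxel units, per axis
    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5
    for sphere in phantom.spheres:
        cs = frame_mean_concentration(
            sphere.concentration0, sphere.isotope, frame_start, frame_duration
        )
        r = sphere.radius
        # bounding box of voxels possibly touched
        lo, hi = [], []
        for a in range(3):
            lo.append(
                max(
                    int(np.floor((sphere.center[a] - r - grid.origin[a]) / grid.spacing[a])) - 1,
                    0,
                )
            )
            hi.append(
                min(
                    int(np.ceil((sphere.center[a] + r - grid.origin[a]) / grid.spacing[a])) + 2,
                    grid.dims[a],
                )
            )
        ax = [
            grid.axis_centers(a)[lo[a] : hi[a]] - sphere.center[a] for a in range(3)
        ]
        # all sub-sample coordinates per axis: (nvox, s)
        subax = [
            (ax[a][:, None] + sub[None, :] * grid.spacing[a]) ** 2 for a in range(3)
        ]
        d2 = (
            subax[0][:, None, None, :, None, None]
            + subax[1][None, :, None, None, :, None]
            + subax[2][None, None, :, None, None, :]
        )
        frac = (d2 < r * r).reshape(
            len(ax[0]), len(ax[1]), len(ax[2]), -1
        ).mean(axis=-1)
        region = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        region += frac * (cs - region)  # mixes with whatever is there (background)

    meta = {}
    if cb > 0:
        meta["true_ratio"] = true_ratio(phantom, frame_start, frame_duration)
    return ActivityImage(
        grid=grid,
        values=values,
        frame_start=frame_start,
        frame_duration=frame_duration,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# builders


def build_phantom(
    diameters_mm=FULL_SPHERE_DIAMETERS_MM,
    sphere_spacing_mm: float = 24.0,
    sphere_concentration0: float = 10_000.0,
    background_concentration0: float = 10_000.0,
    voxel_mm: float = 2.0,
    margin_mm: float = 18.0,
    background_halfwidth_mm: float = 24.0,
    center_offset_mm=(0.0, 0.0, 0.0),
    min_background_ml: float = 250.0,
) -> tuple[PhantomSpec, VoxelGrid]:
    """Construct a string-of-spheres phantom and a grid that fits it.

    Spheres are collinear along z (the string axis), centers snapped to
    voxel centers, spaced ``sphere_spacing_mm`` apart. The background is a
    box of square cross-section (half-width ``background_halfwidth_mm``)
    that encloses the string; the reference source is a separate box beyond
    the string's far end. ``margin_mm`` of empty grid (≥ 4× the default
    4.5-mm system FWHM) surrounds all active material. Concentrations at
    t=0 default to 1:1 sphere:background.

    Returns the phantom together with its natural ``VoxelGrid``.
    """
    h = voxel_mm
    n_sph = len(diameters_mm)
    spacing_vox = int(round(sphere_spacing_mm / h))
    if spacing_vox < 1:
        raise ValueError("sphere spacing below one voxel")

    # in-plane: background half-width + margin on each side, odd voxel count
    # so the string axis passes through voxel centers
    half_vox = int(np.ceil((background_halfwidth_mm + margin_mm) / h))
    nxy = 2 * half_vox + 1
    c_xy = half_vox * h  # physical in-plane coordinate of the axis

    # axial layout (voxel indices): background box, spheres, reference source
    bg_z0 = int(round(margin_mm / h))
    sph_pad_vox = int(np.ceil((max(diameters_mm) / 2 + 4.0) / h))
    sph_z = [bg_z0 + sph_pad_vox + i * spacing_vox for i in range(n_sph)]
    bg_z1 = sph_z[-1] + sph_pad_vox + 1  # exclusive
    ref_gap_vox = int(np.ceil(8.0 / h))
    ref_side_vox = int(np.ceil(44.0 / h))
    ref_z0 = bg_z1 + ref_gap_vox
    ref_z1 = ref_z0 + ref_side_vox
    nz = ref_z1 + int(np.ceil(margin_mm / h))

    grid = VoxelGrid(dims=(nxy, nxy, nz), spacing=(h, h, h))

    spheres = tuple(
        SphereSpec(
            diameter=float(d),
            center=(
                c_xy + center_offset_mm[0],
                c_xy + center_offset_mm[1],
                z * h + center_offset_mm[2],
            ),
            concentration0=sphere_concentration0,
            isotope=F18,
        )
        for d, z in zip(diameters_mm, sph_z)
    )

    bg_len_vox = bg_z1 - bg_z0
    bg_region = BoxRegion(
        center=(c_xy, c_xy, (bg_z0 + bg_z1 - 1) / 2.0 * h),
        size=(2 * background_halfwidth_mm, 2 * background_halfwidth_mm, bg_len_vox * h),
    )
    if bg_region.volume_ml < min_background_ml:
        raise ValueError(
            f"background volume {bg_region.volume_ml:.0f} mL < {min_background_ml:g} mL; "
            "increase sphere count, spacing or cross-section"
        )
    background = BackgroundSpec(region=bg_region, concentration0=background_concentration0)

    ref_center_z = (ref_z0 + ref_z1 - 1) / 2.0 * h
    reference_source = BoxRegion(
        center=(c_xy, c_xy, ref_center_z),
        size=(ref_side_vox * h, ref_side_vox * h, ref_side_vox * h),
    )

    # measurement VOIs: nominal-volume boxes with exact voxel counts
    vox_ml = grid.voxel_volume_ml
    ref_dims = near_cubic_dims(int(round(6.0 / vox_ml)))
    reference_voi = BoxRegion(
        center=(c_xy, c_xy, ref_center_z),
        size=(ref_dims[0] * h, ref_dims[1] * h, ref_dims[2] * h),
    )
    bg_dims = near_cubic_dims(int(round(15.0 / vox_ml)))
    # offset the background VOI off the string axis so it clears the spheres
    bg_voi_x = c_xy + background_halfwidth_mm - bg_dims[0] * h / 2.0 - 2.0
    bg_voi_z0 = bg_z0 + 2
    background_voi = BoxRegion(
        center=(
            bg_voi_x,
            c_xy,
            (2 * bg_voi_z0 + bg_dims[2] - 1) / 2.0 * h,
        ),
        size=(bg_dims[0] * h, bg_dims[1] * h, bg_dims[2] * h),
    )

    phantom = PhantomSpec(
        spheres=spheres,
        background=background,
        reference_source=reference_source,
        reference_voi=reference_voi,
        background_voi=background_voi,
    )
    return phantom, grid


def default_phantom(**kwargs) -> tuple[PhantomSpec, VoxelGrid]:
    """The twelve-sphere reference phantom on its natural grid."""
    return build_phantom(FULL_SPHERE_DIAMETERS_MM, **kwargs)


def study_phantom(**kwargs) -> tuple[PhantomSpec, VoxelGrid]:
    """Reduced phantom with one sphere per unique diameter {3..12} mm.

    The experiment pipeline sweeps per-diameter recovery, for which the
    duplicate diameters of the full set add nothing; dropping them shortens
    the string (and the grid) by ~40%.
    """
    return build_phantom(STUDY_DIAMETERS_MM, **kwargs)
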