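"""EM-family iterative reconstruction with optional resolution modeling.

The reconstruction is standard (ordered-subset) maximum-likelihood
expectation-maximization for Poisson data,

    x ← x / s · Bᵀ( y / B x ),        s = Bᵀ 1,

where B is the forward model. Without resolution modeling B = P, the
parallel-beam projector; with it B = P ∘ G, an image-space Gaussian blur of
FWHM ``psf_fwhm`` applied before projection (and its adjoint after
backprojection). This image-space PSF model is the simplest member of the
resolution-modeling family and reproduces its characteristic artifact
class: Gibbs-type edge overshoot, recovery coefficients above 1 for
near-resolution-sized objects, and slowed convergence.

An optional Gaussian post-filter is applied once, after the final
iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .acquisition import SinogramFrame, gaussian_blur_mm, system_matrix
from .grid import ActivityImage, VoxelGrid

__all__ = [
    "ReconParams",
    "ReconResult",
    "LinearSystem",
    "MatrixSystem",
    "IdentitySystem",
    "SliceParallelSystem",
    "PSFSystem",
    "build_system",
    "sensitivity_image",
    "em_update",
    "loglik",
    "reconstruct",
    "gaussian_postfilter",
]


@dataclass(frozen=True)
class ReconParams:
    """EM configuration.

    Defaults follow the clinical presets being emulated: 21 subsets with
    resolution modeling, 16 without; matched 4.5-mm PSF kernel; 2-mm
    Gaussian post-filter (0 disables).
    """

    iterations: int = 4
    subsets: int | None = None  # None -> 21 if psf_modeled else 16
    psf_modeled: bool = False
    psf_fwhm: float = 4.5
    postfilter_fwhm: float = 2.0

    def __post_init__(self) -> None:
        if self.subsets is None:
            object.__setattr__(self, "subsets", 21 if self.psf_modeled else 16)
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")
        if self.psf_fwhm < 0 or self.postfilter_fwhm < 0:
            raise ValueError("kernel widths must be >= 0")

    @property
    def label(self) -> str:
        psf = "psf" if self.psf_modeled else "nopsf"
        return f"{psf}-i{self.iterations}-s{self.subsets}-f{self.postfilter_fwhm:g}"


@dataclass
class ReconResult:
    image: ActivityImage
    params: ReconParams
    loglik_trace: list[float] = field(default_factory=list)
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    """Unfiltered image values after each full iteration (1-based keys)."""


# ---------------------------------------------------------------------------
# linear system models


class LinearSystem:
    """Forward/adjoint pair; subclasses define ``project``/``backproject``."""

    def project(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backproject(self, y: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MatrixSystem(LinearSystem):
    """Explicit (dense or sparse) matrix acting on flat vectors — for toy
    problems and oracle tests."""

    def __init__(self, matrix):
        self.matrix = matrix

    def project(self, x):
        return self.matrix @ x

    def backproject(self, y):
        return self.matrix.T @ y


class IdentitySystem(LinearSystem):
    """Data live in image space (image-mode acquisition)."""

    def project(self, x):
        return x

    def backproject(self, y):
        return y


class SliceParallelSystem(LinearSystem):
    """Slice-stacked 2D parallel projection over a subset of angles."""

    def __init__(self, grid: VoxelGrid, geometry, angle_indices=None):
        self.grid = grid
        self.geometry = geometry
        full = system_matrix(geometry)
        if angle_indices is None:
            angle_indices = np.arange(geometry.n_angles)
        self.angle_indices = np.asarray(angle_indices)
        rows = geometry.angle_rows(self.angle_indices)
        self.matrix = full[rows].tocsr()
        self.matrix_t = self.matrix.T.tocsr()

    @property
    def data_shape(self):
        return (len(self.angle_indices), self.geometry.n_radial, self.grid.dims[2])

    def project(self, x):
        nx, ny, nz = self.grid.dims
        return (self.matrix @ x.reshape(nx * ny, nz)).reshape(self.data_shape)

    def backproject(self, y):
        nx, ny, nz = self.grid.dims
        return (self.matrix_t @ y.reshape(-1, nz)).reshape(nx, ny, nz)


class PSFSystem(LinearSystem):
    """B = base ∘ G with G a self-adjoint Gaussian blur (resolution model)."""

    def __init__(self, base: LinearSystem, fwhm_mm: float, grid: VoxelGrid):
        self.base = base
        self.fwhm_mm = fwhm_mm
        self.grid = grid

    def project(self, x):
        return self.base.project(
            gaussian_blur_mm(x, self.fwhm_mm, self.grid.spacing)
        )

    def backproject(self, y):
        return gaussian_blur_mm(
            self.base.backproject(y), self.fwhm_mm, self.grid.spacing
        )


def build_system(
    frame: SinogramFrame, params: ReconParams, angle_indices=None
) -> LinearSystem:
    """System model matching a frame's acquisition mode and recon params."""
    if frame.mode == "image":
        base: LinearSystem = IdentitySystem()
    else:
        base = SliceParallelSystem(frame.grid, frame.geometry, angle_indices)
    if params.psf_modeled and params.psf_fwhm > 0:
        return PSFSystem(base, params.psf_fwhm, frame.grid)
    return base


# ---------------------------------------------------------------------------
# EM core


def sensitivity_image(system: LinearSystem, data_shape) -> np.ndarray:
    """Bᵀ1 — the EM normalization term; ≥ 0, positive inside the FOV."""
    return system.backproject(np.ones(data_shape))


def em_update(
    x: np.ndarray,
    data: np.ndarray,
    system: LinearSystem,
    sensitivity: np.ndarray | None = None,
    eps_rel: float = 1e-12,
) -> np.ndarray:
    """One multiplicative EM step x ← x/s · Bᵀ(y / Bx).

    Non-negative in, non-negative out; zero voxels stay zero; voxels with
    zero sensitivity are masked out rather than divided. The ratio
    denominator is guarded by ``eps_rel · max(Bx)``.
    """
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if sensitivity is None:
        sensitivity = sensitivity_image(system, data.shape)
    proj = system.project(x)
    eps = eps_rel * proj.max() if proj.size and proj.max() > 0 else eps_rel
    ratio = data / (proj + eps)
    update = system.backproject(ratio)
    out = np.zeros_like(x)
    ok = sensitivity > 0
    out[ok] = x[ok] * update[ok] / sensitivity[ok]
    return out


def loglik(x: np.ndarray, data: np.ndarray, system: LinearSystem) -> float:
    """Poisson log-likelihood Σ y·log(Bx) − (Bx), with 0·log 0 := 0."""
    proj = system.project(x)
    with np.errstate(divide="ignore"):
        terms = xlogy(data, proj) - proj
    # bins with y>0 but Bx=0 contribute -inf, as they should
    return float(terms.sum())


def _bit_reversed_order(n: int) -> list[int]:
    """Deterministic maximally-interleaved subset visiting order."""
    if n == 1:
        return [0]
    bits = (n - 1).bit_length()
    seq = []
    for i in range(1 << bits):
        r = int(format(i, f"0{bits}b")[::-1], 2)
        if r < n:
            seq.append(r)
    return seq


def reconstruct(
    frame: SinogramFrame,
    params: ReconParams,
    initial: np.ndarray | None = None,
    track_loglik: bool = False,
    keep_snapshots: bool = False,
) -> ReconResult:
    """Run OSEM (MLEM when subsets=1) on one frame.

    Subsets partition the angle set by interleaving (subset j holds angles
    j, j+S, ...), visited in a fixed bit-reversed order; the post-filter is
    applied once after the final iteration. Deterministic given inputs.
    """
    s = params.subsets
    if frame.mode == "image":
        if s != 1:
            raise ValueError("image-mode data supports subsets=1 only")
        subsets_data = [frame.counts]
        systems = [build_system(frame, params)]
    else:
        n_angles = frame.geometry.n_angles
        if n_angles % s != 0:
            raise ValueError(f"subsets={s} does not divide n_angles={n_angles}")
        subsets_data = []
        systems = []
        for j in range(s):
            idx = np.arange(j, n_angles, s)
            systems.append(build_system(frame, params, angle_indices=idx))
            subsets_data.append(frame.counts[idx])

    sens = [sensitivity_image(sys_j, d.shape) for sys_j, d in zip(systems, subsets_data)]
    full_system = build_system(frame, params)
    total_counts = frame.counts.sum()
    full_sens_total = sum(sj.sum() for sj in sens)
    x0_val = total_counts / full_sens_total if full_sens_total > 0 else 1.0
    x = np.full(frame.grid.dims, x0_val) if initial is None else initial.astype(float).copy()

    order = _bit_reversed_order(s)
    trace: list[float] = []
    snapshots: dict[int, np.ndarray] = {}
    for it in range(1, params.iterations + 1):
        for j in order:
            x = em_update(x, subsets_data[j], systems[j], sens[j])
        if track_loglik:
            trace.append(loglik(x, frame.counts, full_system))
        if keep_snapshots:
            snapshots[it] = x.copy()

    final = gaussian_blur_mm(x, params.postfilter_fwhm, frame.grid.spacing)
    image = ActivityImage(
        grid=frame.grid,
        values=final,
        frame_start=frame.frame_start,
        frame_duration=frame.frame_duration,
        meta={**frame.meta, "recon": params.label},
    )
    return ReconResult(image=image, params=params, loglik_trace=trace, snapshots=snapshots)


def gaussian_postfilter(img: ActivityImage, fwhm_mm: float) -> ActivityImage:
    """Gaussian smoothing of a reconstructed volume; ``fwhm=0`` is identity."""
    return img.copy_with(gaussian_blur_mm(img.values, fwhm_mm, img.grid.spacing))
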