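import numpy as np
import pytest

from psfrc import (
    AcquisitionConfig,
    ActivityImage,
    ReconParams,
    VoxelGrid,
    gaussian_postfilter,
    loglik,
    reconstruct,
    simulate_frame,
)
from psfrc.acquisition import SinogramFrame, geometry_for_grid
from psfrc.reconstruction import (
    IdentitySystem,
    MatrixSystem,
    PSFSystem,
    SliceParallelSystem,
    _bit_reversed_order,
    em_update,
    sensitivity_image,
)


@pytest.fixture
def small_grid():
    return VoxelGrid((21, 21, 3), (2.0, 2.0, 2.0))


def noiseless_frame(img, n_angles=24):
    cfg = AcquisitionConfig(
        n_angles=n_angles, target_counts=1e6, noiseless=True, system_fwhm=0.0
    )
    return simulate_frame(img, cfg)


class TestSensitivity:
    def test_flat_inside_fov_without_psf(self, small_grid):
        geom = geometry_for_grid(small_grid, AcquisitionConfig(n_angles=48))
        sys_full = SliceParallelSystem(small_grid, geom)
        sens = sensitivity_image(sys_full, (48, geom.n_radial, 3))
        interior = sens[3:-3, 3:-3, 1]
        assert (interior.max() - interior.min()) / interior.mean() < 0.01

    def test_psf_with_zero_fwhm_equals_plain(self, small_grid):
        geom = geometry_for_grid(small_grid, AcquisitionConfig(n_angles=24))
        base = SliceParallelSystem(small_grid, geom)
        wrapped = PSFSystem(base, 0.0, small_grid)
        shape = (24, geom.n_radial, 3)
        assert np.allclose(
            sensitivity_image(base, shape), sensitivity_image(wrapped, shape)
        )

    def test_subset_sensitivities_sum_to_full(self, small_grid):
        geom = geometry_for_grid(small_grid, AcquisitionConfig(n_angles=24))
        full = sensitivity_image(
            SliceParallelSystem(small_grid, geom), (24, geom.n_radial, 3)
        )
        parts = np.zeros_like(full)
        for j in range(4):
            idx = np.arange(j, 24, 4)
            parts += sensitivity_image(
                SliceParallelSystem(small_grid, geom, idx),
                (6, geom.n_radial, 3),
            )
        assert np.allclose(parts, full, rtol=1e-12)


class TestEMUpdate:
    def test_fixed_point(self):
        a = np.array([[2.0, 1.0], [1.0, 3.0], [0.5, 0.5]])
        system = MatrixSystem(a)
        x = np.array([1.5, 2.5])
        y = a @ x
        out = em_update(x, y, system)
        assert np.allclose(out, x, rtol=1e-10)

    def test_toy_system_converges_to_direct_solve(self):
        a = np.array([[2.0, 1.0], [1.0, 3.0]])
        x_true = np.array([1.0, 2.0])
        y = a @ x_true
        system = MatrixSystem(a)
        x = np.ones(2)
        for _ in range(500):
            x = em_update(x, y, system)
        assert np.allclose(x, np.linalg.solve(a, y), rtol=1e-6)

    def test_total_count_identity(self):
        rng = np.random.default_rng(2)
        a = rng.random((20, 8)) + 0.05
        y = rng.poisson(30.0, size=20).astype(float)
        system = MatrixSystem(a)
        sens = sensitivity_image(system, y.shape)
        x = np.full(8, y.sum() / sens.sum())
        for _ in range(5):
            x = em_update(x, y, system, sens)
            assert np.dot(sens, x) == pytest.approx(y.sum(), rel=1e-8)

    def test_nonnegativity_and_zero_preservation(self):
        rng = np.random.default_rng(4)
        a = rng.random((15, 6)) + 0.01
        y = rng.poisson(20.0, size=15).astype(float)
        system = MatrixSystem(a)
        x = rng.random(6)
        x[2] = 0.0
        out = em_update(x, y, system)
        assert (out >= 0).all()
        assert out[2] == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            em_update(np.array([-1.0, 1.0]), np.ones(2), MatrixSystem(np.eye(2)))


class TestLogLik:
    def test_zero_data_zero_image(self):
        assert loglik(np.zeros(3), np.zeros(3), MatrixSystem(np.eye(3))) == 0.0

    def test_stationary_under_scalar_rescaling(self):
        rng = np.random.default_rng(1)
        a = rng.random((12, 5)) + 0.1
        x = rng.random(5) + 0.1
        y = a @ x
        system = MatrixSystem(a)
        best = loglik(x, y, system)
        for k in (0.5, 0.9, 1.1, 2.0):
            assert loglik(k * x, y, system) < best

    def test_mlem_trace_nondecreasing(self):
        rng = np.random.default_rng(6)
        a = rng.random((30, 10)) + 0.05
        x_true = rng.random(10) + 0.2
        y = rng.poisson(50 * (a @ x_true)).astype(float)
        system = MatrixSystem(a)
        sens = sensitivity_image(system, y.shape)
        x = np.full(10, y.sum() / sens.sum())
        prev = loglik(x, y, system)
        for _ in range(50):
            x = em_update(x, y, system, sens)
            cur = loglik(x, y, system)
            assert cur >= prev - 1e-9 * abs(prev)
            prev = cur


class TestReconstruct:
    def test_uniform_phantom_reconstructs_uniform(self, small_grid):
        img = ActivityImage(small_grid, np.full(small_grid.dims, 7.0))
        for psf in (False, True):
            # data blurred consistently with the reconstruction model
            cfg = AcquisitionConfig(
                n_angles=48,
                target_counts=1e6,
                noiseless=True,
                system_fwhm=4.5 if psf else 0.0,
            )
            frame = simulate_frame(img, cfg)
            params = ReconParams(
                iterations=3, subsets=1, psf_modeled=psf, postfilter_fwhm=0.0
            )
            res = reconstruct(frame, params)
            interior = res.image.values[5:-5, 5:-5, 1]
            assert (interior.max() - interior.min()) / interior.mean() < 0.005

    def test_mlem_loglik_trace_nondecreasing_on_noisy_data(self, small_grid):
        vals = np.zeros(small_grid.dims)
        vals[8:13, 8:13, :] = 10.0
        img = ActivityImage(small_grid, vals)
        cfg = AcquisitionConfig(n_angles=24, target_counts=5e4, system_fwhm=0.0)
        frame = simulate_frame(img, cfg, seed=9)
        params = ReconParams(iterations=10, subsets=1, postfilter_fwhm=0.0)
        res = reconstruct(frame, params, track_loglik=True)
        t = np.array(res.loglik_trace)
        assert np.all(np.diff(t) >= -1e-9 * np.abs(t[:-1]))

    def test_osem_deterministic_and_subset_order_fixed(self, small_grid):
        vals = np.zeros(small_grid.dims)
        vals[9:12, 9:12, :] = 5.0
        img = ActivityImage(small_grid, vals)
        cfg = AcquisitionConfig(n_angles=24, target_counts=1e5)
        frame = simulate_frame(img, cfg, seed=2)
        params = ReconParams(iterations=2, subsets=4, postfilter_fwhm=2.0)
        r1 = reconstruct(frame, params)
        r2 = reconstruct(frame, params)
        assert np.array_equal(r1.image.values, r2.image.values)

    def test_subsets_must_divide_angles(self, small_grid):
        img = ActivityImage(small_grid, np.ones(small_grid.dims))
        frame = noiseless_frame(img, n_angles=24)
        with pytest.raises(ValueError, match="divide"):
            reconstruct(frame, ReconParams(iterations=1, subsets=7))

    def test_image_mode_em_deconvolution(self, small_grid):
        vals = np.zeros(small_grid.dims)
        vals[10, 10, 1] = 100.0
        img = ActivityImage(small_grid, vals)
        cfg = AcquisitionConfig(mode="image", target_counts=1e6, noiseless=True)
        frame = simulate_frame(img, cfg)
        params = ReconParams(
            iterations=50, subsets=1, psf_modeled=True, psf_fwhm=4.5, postfilter_fwhm=0.0
        )
        res = reconstruct(frame, params)
        # EM deconvolution re-concentrates the blurred point
        assert res.image.values[10, 10, 1] > 0.5 * frame.counts.max() * 2
        with pytest.raises(ValueError, match="subsets=1"):
            reconstruct(frame, ReconParams(iterations=1, subsets=4, psf_modeled=True))

    def test_result_nonnegative(self, small_grid):
        vals = np.zeros(small_grid.dims)
        vals[9:12, 9:12, :] = 5.0
        frame = simulate_frame(
            ActivityImage(small_grid, vals),
            AcquisitionConfig(n_angles=24, target_counts=2e4),
            seed=8,
        )
        res = reconstruct(frame, ReconParams(iterations=3, subsets=4))
        assert (res.image.values >= 0).all()


class TestPostfilter:
    def test_zero_fwhm_identity(self, small_grid):
        rng = np.random.default_rng(0)
        img = ActivityImage(small_grid, rng.random(small_grid.dims))
        out = gaussian_postfilter(img, 0.0)
        assert np.array_equal(out.values, img.values)

    def test_gaussian_semigroup(self):
        # two successive filters a then b equal one filter √(a²+b²); holds
        # to high accuracy once σ is a voxel or more
        grid = VoxelGrid((40, 40, 40), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(1)
        img = ActivityImage(grid, rng.random(grid.dims))
        a, b = 5.0, 7.0
        twice = gaussian_postfilter(gaussian_postfilter(img, a), b).values
        once = gaussian_postfilter(img, float(np.hypot(a, b))).values
        core = (slice(8, -8),) * 3
        denom = np.abs(once[core]).max()
        assert np.abs(twice[core] - once[core]).max() / denom < 1e-6

    def test_filter_reduces_hot_sphere_max(self):
        grid = VoxelGrid((25, 25, 25), (2.0, 2.0, 2.0))
        vals = np.zeros(grid.dims)
        x, y, z = grid.meshgrid()
        c = 24.0
        vals[((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) < 5.0**2] = 10.0
        img = ActivityImage(grid, vals)
        assert gaussian_postfilter(img, 4.0).values.max() < img.values.max()


class TestSubsetOrder:
    @pytest.mark.parametrize("n", [1, 2, 3, 8, 16, 21])
    def test_bit_reversed_order_is_permutation(self, n):
        order = _bit_reversed_order(n)
        assert sorted(order) == list(range(n))

    def test_interleaving_separates_neighbors(self):
        order = _bit_reversed_order(16)
        assert order[0] == 0 and order[1] == 8


def test_recon_params_defaults_and_validation():
    assert ReconParams(psf_modeled=True).subsets == 21
    assert ReconParams(psf_modeled=False).subsets == 16
    with pytest.raises(ValueError):
        ReconParams(iterations=0)
    with pytest.raises(ValueError):
        ReconParams(postfilter_fwhm=-2.0)


def test_identity_system_roundtrip():
    x = np.arange(5.0)
    s = IdentitySystem()
    assert np.array_equal(s.project(x), x)
    assert np.array_equal(s.backproject(x), x)
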