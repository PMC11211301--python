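import numpy as np
import pytest
from scipy.optimize import curve_fit

from spectrc.acquisition import (
    MAIN_WINDOW_KEV,
    SIDE_WINDOW_KEV,
    OrbitSpec,
    PSFModel,
    ScatterModel,
    SpectProjector,
    add_scatter,
    auto_contour_orbit,
    calibrate_scale,
    make_view_angles,
    scale_and_poisson,
    tew_estimate,
)
from spectrc.phantom import (
    PhantomConfig,
    VoxelGrid,
    VoxelPhantom,
    enumerate_permutations,
    build_phantom,
)


def _ball_phantom(radius_mm=60.0, voxel=6.0, n=32):
    """Phantom whose body is a ball, for rotationally symmetric orbits."""
    grid = VoxelGrid.centered((n, n, n // 2), voxel)
    x = grid.axis_coords(0)[:, None, None]
    y = grid.axis_coords(1)[None, :, None]
    z = grid.axis_coords(2)[None, None, :]
    mu = 0.0137 * ((x**2 + y**2 + z**2) <= radius_mm**2)
    cfg = PhantomConfig.nema_spect()
    perm = enumerate_permutations(cfg.diameters)[0]
    act = np.zeros(grid.shape)
    return VoxelPhantom(cfg, perm, grid, grid, act, mu, {})


class TestOrbit:
    def test_spherical_body_gives_constant_radius(self):
        ph = _ball_phantom(radius_mm=60.0, voxel=6.0)
        orbit = auto_contour_orbit(ph, margin=30.0, angles_deg=make_view_angles(12))
        r = np.array(orbit.radius_mm)
        assert np.allclose(r, r[0], atol=6.0)  # within one voxel
        assert abs(r.mean() - 90.0) < 6.0

    def test_elliptic_body_wider_laterally(self, spect_config, small_grid):
        perm = enumerate_permutations(spect_config.diameters)[0]
        ph = build_phantom(spect_config, perm, small_grid, small_grid)
        orbit = auto_contour_orbit(ph, 20.0, make_view_angles(12))
        r = dict(zip(orbit.angles_deg, orbit.radius_mm))
        assert r[0.0] > r[90.0]  # 300 mm wide vs 230 mm tall body

    def test_margin_additivity(self, spect_config, small_grid):
        perm = enumerate_permutations(spect_config.diameters)[0]
        ph = build_phantom(spect_config, perm, small_grid, small_grid)
        angles = make_view_angles(6)
        r1 = np.array(auto_contour_orbit(ph, 10.0, angles).radius_mm)
        r2 = np.array(auto_contour_orbit(ph, 35.0, angles).radius_mm)
        assert np.allclose(r2 - r1, 25.0)

    def test_couch_clearance_breaks_symmetry_from_below(self, spect_config, small_grid):
        perm = enumerate_permutations(spect_config.diameters)[0]
        ph = build_phantom(spect_config, perm, small_grid, small_grid)
        angles = make_view_angles(12)
        orbit = auto_contour_orbit(ph, 20.0, angles, couch_clearance=60.0)
        r = dict(zip(orbit.angles_deg, orbit.radius_mm))
        assert r[270.0] == pytest.approx(r[90.0] + 60.0)

    def test_negative_margin_rejected(self, spect_config, small_grid):
        perm = enumerate_permutations(spect_config.diameters)[0]
        ph = build_phantom(spect_config, perm, small_grid, small_grid)
        with pytest.raises(ValueError):
            auto_contour_orbit(ph, -1.0, make_view_angles(6))


def _orbit_for(grid, n_views=12, radius=250.0):
    return OrbitSpec(tuple(make_view_angles(n_views // 2)), (radius,) * n_views)


class TestProjector:
    def test_count_conservation_without_blur_or_attenuation(self):
        # odd grid: the center voxel sits exactly on the rotation axis,
        # so every view sees its full emission
        grid = VoxelGrid.centered((33, 33, 8), 9.6)
        x = np.zeros(grid.shape)
        x[16, 16, 4] = 3.7
        proj = SpectProjector(grid, _orbit_for(grid))
        p = proj.forward(x)
        assert np.allclose(p.sum(axis=(1, 2)), 3.7, rtol=1e-12)

    def test_beer_lambert_closed_form(self):
        # axis-aligned views over a uniform attenuator: the central
        # voxel's emission is attenuated by exp(-mu t) with t the exact
        # half-depth path to the detector-side grid edge
        grid = VoxelGrid.centered((33, 33, 8), 9.6)
        mu0 = 0.01
        mu = np.full(grid.shape, mu0)
        x = np.zeros(grid.shape)
        x[16, 16, 4] = 1.0
        orbit = OrbitSpec((0.0, 90.0, 180.0, 270.0), (300.0,) * 4)
        proj = SpectProjector(grid, orbit, mu_map=mu)
        p = proj.forward(x)
        t = (16 + 0.5) * grid.voxel_size[0]
        assert np.allclose(p.sum(axis=(1, 2)), np.exp(-mu0 * t), rtol=1e-10)

    def test_profile_fwhm_matches_distance_dependent_model(self):
        grid = VoxelGrid.centered((64, 64, 8), 3.0)
        psf = PSFModel(intrinsic_fwhm=4.0, slope=0.055)
        orbit = OrbitSpec((0.0,), (220.0,))
        x = np.zeros(grid.shape)
        x[32, 32, 4] = 1.0  # source on the axis, D = 220 mm - x[32]
        proj = SpectProjector(grid, orbit, psf=psf)
        profile = proj.forward(x)[0][:, 4]
        yc = grid.axis_coords(1)

        def gauss(y, a, mu, sig):
            return a * np.exp(-0.5 * ((y - mu) / sig) ** 2)

        popt, _ = curve_fit(gauss, yc, profile, p0=(profile.max(), 0.0, 5.0))
        fitted_fwhm = 2.3548 * abs(popt[2])
        expected = psf.fwhm(220.0 - grid.axis_coords(0)[32])
        assert abs(fitted_fwhm / expected - 1) < 0.05

    def test_linearity(self, small_grid, rng):
        proj = SpectProjector(small_grid, _orbit_for(small_grid), psf=PSFModel())
        x = rng.random(small_grid.shape)
        y = rng.random(small_grid.shape)
        lhs = proj.forward(2.5 * x - 0.5 * y)
        rhs = 2.5 * proj.forward(x) - 0.5 * proj.forward(y)
        assert np.allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("with_psf", [False, True], ids=["geom", "psf"])
    @pytest.mark.parametrize("bin_factor", [1, 2])
    def test_adjoint_identity(self, small_grid, rng, with_psf, bin_factor):
        mu = 0.0137 * (rng.random(small_grid.shape) > 0.5)
        proj = SpectProjector(
            small_grid,
            _orbit_for(small_grid),
            psf=PSFModel() if with_psf else None,
            mu_map=mu,
            scale=17.0,
            bin_factor=bin_factor,
        )
        x = rng.random(small_grid.shape)
        y = rng.random((12, *proj.bin_shape))
        lhs = np.vdot(proj.forward(x), y)
        rhs = np.vdot(x, proj.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_psf_fwhm_monotone_in_distance(self):
        psf = PSFModel()
        d = np.linspace(0, 400, 50)
        f = psf.fwhm(d)
        assert np.all(np.diff(f) >= 0)
        assert f[0] == pytest.approx(psf.intrinsic_fwhm)


class TestScatterAndNoise:
    def test_zero_scatter_fraction_is_identity(self, rng):
        primary = rng.random((6, 16, 8))
        main, lo, up, true = add_scatter(primary, ScatterModel(scatter_fraction=0), (4.8, 4.8))
        assert np.array_equal(main, primary)
        assert not lo.any() and not up.any()

    def test_scatter_mass_preserved_for_central_object(self):
        primary = np.zeros((4, 64, 64))
        primary[:, 24:40, 24:40] = 10.0  # compact, far from edges
        model = ScatterModel(scatter_fraction=0.2, kernel_fwhm=20.0)
        main, _, _, _ = add_scatter(primary, model, (4.8, 4.8))
        assert main.sum() == pytest.approx(primary.sum() * 1.2, rel=1e-6)

    def test_tew_recovers_injected_scatter(self, rng):
        # uniform-disk-like primary; noise-free windows reproduce the
        # injected scatter exactly through the TEW trapezoid
        primary = np.zeros((4, 32, 32))
        primary[:, 8:24, 8:24] = rng.random((4, 16, 16)) + 1.0
        model = ScatterModel(scatter_fraction=0.3, kernel_fwhm=30.0, lower_fraction=0.6)
        main, lo, up, true = add_scatter(primary, model, (4.8, 4.8))
        est = tew_estimate(lo, up)
        assert np.allclose(est, true, rtol=1e-12, atol=1e-12)
        assert np.allclose(main - true, primary)

    def test_tew_trapezoid_formula(self):
        lo = np.full((2, 4, 4), 5.0 * SIDE_WINDOW_KEV)
        up = np.full((2, 4, 4), 5.0 * SIDE_WINDOW_KEV)
        est = tew_estimate(lo, up)
        assert np.allclose(est, 5.0 * MAIN_WINDOW_KEV)
        assert tew_estimate(np.zeros((1, 2, 2)), np.zeros((1, 2, 2))).sum() == 0

    def test_tew_zero_width_rejected(self):
        with pytest.raises(ValueError):
            tew_estimate(np.ones((1, 2, 2)), np.ones((1, 2, 2)), w_main=0.0)

    def test_poisson_zero_expectation_stays_zero(self):
        orbit = OrbitSpec((0.0, 90.0), (200.0, 200.0))
        z = np.zeros((2, 8, 8))
        ps = scale_and_poisson(z, z, z, orbit, (4.8, 4.8), scale=100.0, seed=7)
        assert not ps.counts_main.any()

    def test_poisson_sample_mean_matches_expectation(self):
        orbit = OrbitSpec((0.0,), (200.0,))
        lam = 100.0
        n = 10_000
        w = np.full((1, n, 1), 1.0)
        ps = scale_and_poisson(w, 0 * w, 0 * w, orbit, (4.8, 4.8), scale=lam, seed=3)
        mean = ps.counts_main.mean()
        assert abs(mean - lam) < 3.0 * np.sqrt(lam / n)

    def test_same_seed_bit_identical(self, rng):
        orbit = OrbitSpec((0.0, 90.0), (200.0, 200.0))
        w = rng.random((2, 8, 8)) * 50
        a = scale_and_poisson(w, w / 3, w / 4, orbit, (4.8, 4.8), 2.0, seed=11)
        b = scale_and_poisson(w, w / 3, w / 4, orbit, (4.8, 4.8), 2.0, seed=11)
        for u, v in (
            (a.counts_main, b.counts_main),
            (a.counts_lower, b.counts_lower),
            (a.counts_upper, b.counts_upper),
        ):
            assert np.array_equal(u, v)

    def test_negative_expectation_rejected(self):
        orbit = OrbitSpec((0.0,), (200.0,))
        w = -np.ones((1, 4, 4))
        with pytest.raises(ValueError):
            scale_and_poisson(w, w, w, orbit, (4.8, 4.8), 1.0, seed=0)

    def test_calibration_hits_target_counts(self, rng):
        counts = rng.random((10, 16, 16)) * 7.0
        s = calibrate_scale(counts, target_counts_per_view=25_000.0)
        assert (counts * s).sum(axis=(1, 2)).mean() == pytest.approx(25_000.0)
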