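import numpy as np
import pytest

from foldflux import (
    FieldRecipe,
    GridSpec,
    coarse_grain_curve,
    directed_to_stochastic_sign_check,
    fit_power_law,
    flux_variance_series,
    fpt_fit,
    generate_fbm_transects,
    generate_field,
    msd_slope,
    prefactor_scaling,
    simulate_brownian_walkers,
    structure_functions,
    time_variance,
    variance_spectrum,
)
from foldflux.grids import FluxGrid3D
from foldflux.turbulence import DegenerateSpectrumError
from oracles import box_counting_dimension


class TestPowerLawFit:
    def test_exact_power_law_zero_residual(self):
        x = np.arange(1.0, 11.0)
        fit = fit_power_law(x, 5 * x**3)
        assert fit.exponent == pytest.approx(3.0, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-6)

    def test_constant_gives_zero_exponent(self):
        x = np.arange(1.0, 8.0)
        assert fit_power_law(x, np.full(7, 4.2)).exponent == pytest.approx(0.0)

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 50, 20)
        y = x**0.7 * np.exp(rng.normal(0, 0.05, 20))
        fit = fit_power_law(x, y)
        assert fit.exponent == pytest.approx(0.7, abs=0.05)

    def test_non_positive_points_excluded_with_warning(self):
        x = np.arange(1.0, 8.0)
        y = x.copy()
        y[2] = -1.0
        with pytest.warns(UserWarning, match="excluding"):
            fit = fit_power_law(x, y)
        assert fit.n_points == 6

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_power_law(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCoarseGraining:
    def test_uniform_field_gives_exactly_L_squared(self):
        grid = generate_field(
            FieldRecipe("uniform", (32, 32, 32), parameters={"value": 3.0})
        )
        curve = coarse_grain_curve(grid, 0)
        np.testing.assert_allclose(
            np.asarray(curve.G_values), [1.0, 4.0, 9.0, 16.0, 25.0], atol=1e-12
        )
        assert curve.fit.exponent == pytest.approx(2.0, abs=1e-12)

    def test_isolated_cells_give_constant_G_and_zero_index(self):
        # at most one visited cell per tile at every L <= 5: G(L) = 1, D = 0
        dims = (4, 32, 32)
        spec = GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), dims=dims)
        j = np.zeros((3, *dims))
        visits = np.zeros(dims)
        j[0][:, ::8, ::8] = 2.0
        visits[:, ::8, ::8] = 1.0
        grid = FluxGrid3D(
            spec=spec, j=j, visits=visits, p=visits / visits.sum(),
            m_trajectories=1, mfpt=1.0,
        )
        curve = coarse_grain_curve(grid, 0)
        np.testing.assert_allclose(np.asarray(curve.G_values), 1.0, atol=1e-12)
        assert curve.fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_fractal_support_dimension_recovered(self):
        target = 1.2
        grid = generate_field(
            FieldRecipe(
                "fractal_support", (8, 64, 64),
                parameters={"box_dimension": target, "axis": 0}, seed=2,
            )
        )
        curve = coarse_grain_curve(grid, 0, L_values=(1, 2, 4, 8, 16))
        assert curve.fit.exponent == pytest.approx(target, abs=0.15)

    def test_generator_support_matches_box_counting_oracle(self):
        from foldflux.synthetic import _fractal_support_2d

        rng = np.random.default_rng(0)
        mask = _fractal_support_2d((64, 64), 1.2, rng)
        dim = box_counting_dimension(mask, [1, 2, 4, 8, 16])
        assert dim == pytest.approx(1.2, abs=0.1)

    def test_region_restriction_selects_g1_interval(self):
        grid = generate_field(
            FieldRecipe("uniform", (32, 32, 32), parameters={"value": 1.0})
        )
        curve = coarse_grain_curve(grid, 0, region=(10.0, 20.0))
        assert curve.fit.exponent == pytest.approx(2.0, abs=1e-12)
        with pytest.raises(ValueError, match="region"):
            coarse_grain_curve(grid, 0, region=(100.0, 200.0))


class TestStructureFunctions:
    def test_constant_field_has_zero_increments(self):
        grid = generate_field(
            FieldRecipe("uniform", (12, 12, 12), parameters={"value": 2.0})
        )
        sf = structure_functions(grid, l_max=6)
        np.testing.assert_allclose(np.asarray(sf.C_ll[sf.counts > 0]), 0.0, atol=1e-20)
        np.testing.assert_allclose(np.asarray(sf.C_lll[sf.counts > 0]), 0.0, atol=1e-20)

    def test_linear_shear_closed_form_fixes_sign_convention(self):
        a = 0.5
        grid = generate_field(
            FieldRecipe("shear", (16, 16, 16), parameters={"slope": a, "axis": 0})
        )
        sf = structure_functions(grid, l_max=8, direction_axis=0)
        l = sf.l_bins[1:9]
        np.testing.assert_allclose(np.asarray(sf.C_ll[1:9]), a**2 * l**2, rtol=1e-12)
        np.testing.assert_allclose(np.asarray(sf.C_lll[1:9]), a**3 * l**3, rtol=1e-12)

    def test_second_order_is_nonnegative_everywhere(self):
        grid = generate_field(FieldRecipe("kolmogorov", (24, 24, 24), seed=9))
        sf = structure_functions(grid, l_max=10, seed=1)
        assert np.all(np.asarray(sf.C_ll[sf.counts > 0]) >= 0)

    def test_too_few_occupied_cells_raise(self):
        dims = (4, 4, 4)
        spec = GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), dims=dims)
        visits = np.zeros(dims)
        visits[0, 0, 0] = 1
        grid = FluxGrid3D(
            spec=spec, j=np.zeros((3, *dims)), visits=visits,
            p=visits / visits.sum(), m_trajectories=1, mfpt=1.0,
        )
        with pytest.raises(ValueError):
            structure_functions(grid, l_max=3)


class TestDirectedToStochastic:
    def test_transition_range_third_moment_is_negative(self):
        grid = generate_field(
            FieldRecipe(
                "directed_to_stochastic", (32, 16, 16),
                parameters={"channel_value": 1.0, "noise_sigma": 0.1}, seed=3,
            )
        )
        sign, value = directed_to_stochastic_sign_check(grid)
        assert sign == -1 and value < 0

    def test_isotropic_zero_mean_field_is_unskewed(self):
        rng = np.random.default_rng(5)
        dims = (20, 20, 20)
        spec = GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), dims=dims)
        visits = np.ones(dims)
        grid = FluxGrid3D(
            spec=spec, j=rng.standard_normal((3, *dims)), visits=visits,
            p=visits / visits.sum(), m_trajectories=1, mfpt=1.0,
        )
        _, value = directed_to_stochastic_sign_check(grid, l_range=(5.0, 15.0))
        sf = structure_functions(grid, l_max=15.0)
        scale = float(np.mean(np.asarray(sf.C_ll[sf.counts > 0]))) ** 1.5
        assert abs(value) < 0.1 * scale

    def test_mirrored_field_keeps_the_sign(self):
        grid = generate_field(
            FieldRecipe(
                "directed_to_stochastic", (32, 16, 16),
                parameters={"channel_value": 1.0, "noise_sigma": 0.1}, seed=3,
            )
        )
        mirrored = FluxGrid3D(
            spec=grid.spec,
            j=np.stack([-grid.j[0][::-1], grid.j[1][::-1], grid.j[2][::-1]]),
            visits=grid.visits[::-1].copy(),
            p=grid.p[::-1].copy(),
            m_trajectories=1, mfpt=1.0,
        )
        sign_fwd, _ = directed_to_stochastic_sign_check(grid)
        sign_rev, _ = directed_to_stochastic_sign_check(mirrored)
        assert sign_fwd == sign_rev == -1


class TestFluxVariance:
    def test_static_fields_give_zero_rate(self):
        field = np.ones((50, 3))
        series = flux_variance_series([field] * 10, np.ones(10), 0.1)
        assert series.eps_pf == pytest.approx(0.0, abs=1e-12)

    def test_random_walk_construction_recovers_rate(self):
        rng = np.random.default_rng(0)
        s2 = 0.04  # per-component step variance per window
        dt = 0.01
        fields = []
        j = rng.normal(0, 1.0, (4000, 3))
        for _ in range(60):
            fields.append(j.copy())
            j = j + rng.normal(0, np.sqrt(s2), (4000, 3))
        series = flux_variance_series(fields, np.ones(60), dt, fit_range_max=0.3)
        expected_rate = 3 * s2 / dt
        assert series.eps_pf == pytest.approx(expected_rate, rel=0.15)

    def test_diffusion_coefficient_is_rate_over_six_exactly(self):
        rng = np.random.default_rng(1)
        fields = [rng.normal(size=(100, 3)) for _ in range(8)]
        series = flux_variance_series(fields, np.ones(8), 0.5)
        assert series.diffusion_coefficient == series.eps_pf / 6.0

    def test_time_variance_runs_on_funnel_ensemble(self, funnel_ensemble):
        spec = GridSpec.from_data(funnel_ensemble.pooled_frames(), 1.0)
        series = time_variance(funnel_ensemble, spec, window_frames=5)
        assert series.eps_pf is not None
        assert series.diffusion_coefficient == series.eps_pf / 6.0
        assert np.all(np.diff(series.dt_values) > 0)


class TestPrefactorScaling:
    def test_smooth_gradient_field_gives_2D_and_3D_of_two(self):
        # block-summing multiplies a smooth field by L^2 (the D = 2 case):
        # A_ll = L^4 and A_lll = L^6 exactly for a linear shear
        grid = generate_field(
            FieldRecipe("shear", (32, 32, 32), parameters={"slope": 0.5, "axis": 0})
        )
        fit2, fit3 = prefactor_scaling(
            grid, L_values=(1, 2, 4), l_range=(4, 12), direction_axis=0
        )
        assert fit2.exponent == pytest.approx(4.0, abs=1e-9)
        assert fit3.exponent == pytest.approx(6.0, abs=1e-9)

    def test_line_support_gives_2D_and_3D_of_one(self):
        grid = generate_field(
            FieldRecipe(
                "fractal_support", (64, 64, 64),
                parameters={"box_dimension": 1.0, "axis": 2, "style": "lines",
                            "line_spacing": 16, "value": 1.0,
                            "ramp_slope": 0.05, "ramp_axis": 2},
                seed=0,
            )
        )
        fit2, fit3 = prefactor_scaling(
            grid, L_values=(1, 2, 4), l_range=(8, 24), direction_axis=2
        )
        assert fit2.exponent == pytest.approx(2.0, abs=0.3)
        assert fit3.exponent == pytest.approx(3.0, abs=0.3)

    def test_baseline_alone_is_identity(self):
        grid = generate_field(
            FieldRecipe("shear", (16, 16, 16), parameters={"slope": 1.0, "axis": 0})
        )
        from foldflux.turbulence import structure_functions as sf_fn

        base = sf_fn(grid, l_max=8, direction_axis=0)
        ratio = np.asarray(base.C_ll[4]) / np.asarray(base.C_ll[4])
        assert ratio == pytest.approx(1.0)


class TestVarianceSpectrum:
    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(2)
        fit, _, _ = variance_spectrum(rng.standard_normal((64, 1024)))
        assert fit.exponent == pytest.approx(0.0, abs=0.1)

    def test_hurst_one_third_gives_kolmogorov_slope(self):
        transects = generate_fbm_transects(64, 1024, hurst=1.0 / 3.0, seed=4)
        fit, _, _ = variance_spectrum(transects)
        assert fit.exponent == pytest.approx(-5.0 / 3.0, abs=0.2)

    def test_pure_sinusoid_is_refused(self):
        t = np.arange(512)
        transects = np.tile(np.sin(2 * np.pi * 12 * t / 512), (4, 1))
        with pytest.raises(DegenerateSpectrumError):
            variance_spectrum(transects)

    def test_short_transects_are_rejected(self):
        with pytest.raises(ValueError, match="256"):
            variance_spectrum(np.zeros((4, 100)))


class TestFirstPassageFit:
    def test_equal_times_give_that_mean(self):
        fit = fpt_fit(np.full(6, 2.0))
        assert fit.waiting_time == 2.0

    def test_large_sample_recovers_generator_mean(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(0.036, size=10_000)
        fit = fpt_fit(times)
        assert fit.waiting_time == pytest.approx(0.036, rel=0.02)

    def test_cdf_is_nondecreasing_within_unit_interval(self, funnel_ensemble):
        fit = fpt_fit(funnel_ensemble)
        assert np.all(np.diff(fit.cdf) >= 0)
        assert 0 < fit.cdf[0] <= 1 and fit.cdf[-1] == pytest.approx(1.0)

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValueError):
            fpt_fit(np.array([0.1, -0.2, 0.3, 0.4, 0.5]))


class TestBrownianDivisor:
    def test_msd_slope_is_six_D_in_three_dimensions(self):
        D0 = 1.7
        paths = simulate_brownian_walkers(10_000, 50, 0.01, D0, seed=1)
        slope = msd_slope(paths, 0.01)
        assert slope / D0 == pytest.approx(6.0, rel=0.05)
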