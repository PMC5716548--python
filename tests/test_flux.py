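import numpy as np
import pytest

from foldflux import (
    GridSpec,
    Trajectory,
    TrajectoryEnsemble,
    box_net_outflow,
    compute_flux_2d,
    compute_flux_3d,
    compute_free_energy,
    compute_stream_function,
    compute_vorticity,
)
from foldflux.grids import FluxGrid2D
from oracles import brute_force_flux


def _ens3(frames, dt=1.0):
    return TrajectoryEnsemble([Trajectory(np.asarray(frames, float), 1.0)], dt, "cv3")


SPEC4 = GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(4, 4, 4))


class TestFluxEstimator3D:
    def test_single_crossing(self):
        grid = compute_flux_3d(_ens3([[0.5, 0, 0], [1.5, 0, 0]]), SPEC4, mfpt=1.0)
        assert grid.j[0][1, 0, 0] == 1.0
        assert np.abs(grid.j).sum() == 1.0  # no other node carries flux

    def test_forward_then_backward_cancels(self):
        grid = compute_flux_3d(
            _ens3([[0.5, 0, 0], [1.5, 0, 0], [0.5, 0, 0]]), SPEC4, mfpt=1.0
        )
        assert np.abs(grid.j).max() == 0.0

    def test_matches_brute_force_oracle(self, random_ensemble_3d):
        spec = GridSpec.from_data(random_ensemble_3d.pooled_frames(), 1.0)
        grid = compute_flux_3d(random_ensemble_3d, spec)
        np.testing.assert_allclose(
            grid.j, brute_force_flux(random_ensemble_3d, spec), atol=1e-12
        )

    def test_plane_conservation(self, random_ensemble_3d):
        # every separating plane carries net flow exactly 1/mfpt
        spec = GridSpec.from_data(random_ensemble_3d.pooled_frames(), 1.0)
        grid = compute_flux_3d(random_ensemble_3d, spec)
        tf = random_ensemble_3d.mfpt
        i_plane = int(round(4.0 - spec.origin[0]))
        total = grid.j[0][i_plane].sum() * spec.spacing[1] * spec.spacing[2]
        assert total == pytest.approx(1.0 / tf, rel=1e-12)

    def test_reversing_trajectories_negates_flux(self, random_ensemble_3d):
        spec = GridSpec.from_data(random_ensemble_3d.pooled_frames(), 1.0)
        fwd = compute_flux_3d(random_ensemble_3d, spec)
        rev = TrajectoryEnsemble(
            [
                Trajectory(t.frames[::-1].copy(), t.first_passage_time)
                for t in random_ensemble_3d.trajectories
            ],
            random_ensemble_3d.frame_interval,
            "cv3",
        )
        bwd = compute_flux_3d(rev, spec, mfpt=random_ensemble_3d.mfpt)
        np.testing.assert_allclose(bwd.j, -fwd.j, atol=1e-12)

    def test_out_of_grid_frame_errors_or_grows(self):
        small = GridSpec(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(2, 2, 2))
        ens = _ens3([[0.5, 0, 0], [5.5, 0, 0]])
        with pytest.raises(ValueError, match="outside the grid"):
            compute_flux_3d(ens, small)
        grown = compute_flux_3d(ens, small, out_of_bounds="grow")
        assert grown.spec.dims[0] >= 6

    def test_probability_only_on_visited_cells(self, random_ensemble_3d):
        spec = GridSpec.from_data(random_ensemble_3d.pooled_frames(), 1.0)
        grid = compute_flux_3d(random_ensemble_3d, spec)
        assert grid.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(grid.p[grid.visits == 0] == 0)


class TestFluxEstimator2D:
    def test_single_crossing(self):
        spec = GridSpec(origin=(0, 0), spacing=(1, 1), dims=(4, 4))
        ens = TrajectoryEnsemble(
            [Trajectory(np.array([[0.5, 0.0], [1.5, 0.0]]), 1.0)], 1.0, "cv2"
        )
        grid = compute_flux_2d(ens, spec, mfpt=1.0)
        assert grid.J[0][1, 0] == 1.0

    def test_within_cell_move_gives_zero_field(self):
        spec = GridSpec(origin=(0, 0), spacing=(1, 1), dims=(4, 4))
        ens = TrajectoryEnsemble(
            [Trajectory(np.array([[1.1, 1.2], [1.3, 1.4]]), 1.0)], 1.0, "cv2"
        )
        grid = compute_flux_2d(ens, spec, mfpt=1.0)
        assert np.abs(grid.J).max() == 0.0

    def test_matches_brute_force_oracle(self, random_ensemble_2d):
        spec = GridSpec.from_data(random_ensemble_2d.pooled_frames(), 1.0)
        grid = compute_flux_2d(random_ensemble_2d, spec)
        np.testing.assert_allclose(
            grid.J, brute_force_flux(random_ensemble_2d, spec), atol=1e-12
        )


class TestBoxOutflow:
    def test_source_sink_free_box_is_exactly_zero(self, random_ensemble_3d):
        res = box_net_outflow(random_ensemble_3d, [2.5, -10, -10], [6.5, 20, 20])
        assert res.net_outflow == 0.0
        assert not res.contains_source and not res.contains_sink

    def test_sink_box_absorbs_one_per_mfpt(self, random_ensemble_3d):
        tf = random_ensemble_3d.mfpt
        res = box_net_outflow(random_ensemble_3d, [8.0, -10, -10], [20, 20, 20])
        assert res.contains_sink
        assert res.net_outflow == pytest.approx(-1.0 / tf, rel=1e-12)

    def test_empty_region_is_zero(self, random_ensemble_3d):
        res = box_net_outflow(random_ensemble_3d, [100, 100, 100], [110, 110, 110])
        assert res.net_outflow == 0.0


class TestFreeEnergy:
    def test_uniform_probability_is_flat_zero(self):
        F = compute_free_energy(np.full(4, 0.25))
        np.testing.assert_allclose(np.asarray(F), 0.0, atol=1e-12)

    def test_four_to_one_ratio_gives_ln4(self):
        F = compute_free_energy(np.array([0.8, 0.2]))
        assert F[0] == 0.0
        assert F[1] == pytest.approx(np.log(4.0))

    def test_zero_probability_cells_are_masked(self):
        F = compute_free_energy(np.array([0.5, 0.5, 0.0]))
        assert F.mask[2]
        assert np.all(np.isfinite(F.compressed()))

    def test_all_zero_probability_raises(self):
        with pytest.raises(ValueError):
            compute_free_energy(np.zeros(4))


def _grid_2d_from_field(J, origin=(-10, -10), spacing=(1.0, 1.0)):
    dims = J.shape[1:]
    spec = GridSpec(origin=origin, spacing=spacing, dims=dims)
    visits = np.ones(dims)
    return FluxGrid2D(
        spec=spec, J=J, visits=visits, p=visits / visits.sum(),
        m_trajectories=1, mfpt=1.0,
    )


def _meshgrid(spec):
    return np.meshgrid(spec.axis_coords(0), spec.axis_coords(1), indexing="ij")


class TestVorticity:
    def test_rigid_rotation_has_omega_two(self):
        spec = GridSpec(origin=(-10, -10), spacing=(1, 1), dims=(21, 21))
        x, y = _meshgrid(spec)
        grid = _grid_2d_from_field(np.stack([-y, x]))
        omega = compute_vorticity(grid)
        np.testing.assert_allclose(omega, 2.0, atol=1e-12)

    def test_uniform_flow_has_zero_vorticity(self):
        grid = _grid_2d_from_field(np.stack([np.ones((9, 9)), 2 * np.ones((9, 9))]))
        np.testing.assert_allclose(compute_vorticity(grid), 0.0, atol=1e-12)

    def test_quadratic_field_is_exact_for_central_differences(self):
        spec = GridSpec(origin=(-10, -10), spacing=(1, 1), dims=(21, 21))
        x, y = _meshgrid(spec)
        grid = _grid_2d_from_field(np.stack([y**2, x**2]))
        omega = compute_vorticity(grid)
        interior = omega[1:-1, 1:-1]
        np.testing.assert_allclose(interior, (2 * x - 2 * y)[1:-1, 1:-1], atol=1e-10)

    def test_gradient_field_has_zero_vorticity(self):
        # J = grad(phi), phi = x^2 + 3xy + y^2: curl must vanish identically
        spec = GridSpec(origin=(-10, -10), spacing=(1, 1), dims=(21, 21))
        x, y = _meshgrid(spec)
        grid = _grid_2d_from_field(np.stack([2 * x + 3 * y, 3 * x + 2 * y]))
        np.testing.assert_allclose(compute_vorticity(grid), 0.0, atol=1e-10)

    def test_too_small_grid_raises(self):
        grid = _grid_2d_from_field(np.zeros((2, 2, 2)), origin=(0, 0))
        with pytest.raises(ValueError):
            compute_vorticity(grid)


class TestStreamFunction:
    def test_uniform_flux_gives_linear_psi(self):
        grid = _grid_2d_from_field(
            np.stack([3 * np.ones((8, 10)), np.zeros((8, 10))]), origin=(0, 5)
        )
        psi = compute_stream_function(grid)
        g2 = grid.spec.axis_coords(1)
        np.testing.assert_allclose(psi, np.tile(3 * (g2 - 5.0), (8, 1)), atol=1e-12)

    def test_zero_flux_gives_zero_psi(self):
        grid = _grid_2d_from_field(np.zeros((2, 6, 6)), origin=(0, 0))
        np.testing.assert_allclose(compute_stream_function(grid), 0.0)

    def test_linear_flux_gives_exact_quadratic_psi(self):
        spec = GridSpec(origin=(0, 0), spacing=(1, 1), dims=(4, 11))
        g2 = spec.axis_coords(1)
        J0 = np.tile(2.0 * g2, (4, 1))
        grid = _grid_2d_from_field(np.stack([J0, np.zeros_like(J0)]), origin=(0, 0))
        psi = compute_stream_function(grid)
        np.testing.assert_allclose(psi, np.tile(g2**2, (4, 1)), atol=1e-12)

    def test_psi_derivative_recovers_flux(self):
        # smooth flux: curvature bounds the trapezoid + central-difference
        # error by spacing^2 * max|J''| / 4 ~ 0.023 here
        spec = GridSpec(origin=(0, 0), spacing=(1, 1), dims=(6, 30))
        g2 = spec.axis_coords(1)
        J0 = np.tile(np.sin(0.3 * g2), (6, 1))
        grid = _grid_2d_from_field(np.stack([J0, np.zeros_like(J0)]), origin=(0, 0))
        psi = compute_stream_function(grid)
        dpsi = np.gradient(psi, 1.0, axis=1)
        np.testing.assert_allclose(dpsi[:, 1:-1], J0[:, 1:-1], atol=0.05)
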