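"""Numerical scheme: steady states, diffusion, FCT transport, moving fronts."""

import numpy as np
import pytest

from nanosens import (Grid, ModelParams, State, TreatmentSchedule, advance,
                      cn_diffuse, fct_advect, initialize, load_checkpoint,
                      normal_glucose_steady, run_simulation, save_checkpoint,
                      steady_state_cell_fraction, update_floating_boundaries)
from nanosens.mechanics import solid_stress_derivative


@pytest.fixture
def grid():
    return Grid(dr=0.5, n=161, R_tumor=2.0, R_tissue=40.0)


class TestSteadyStateCellFraction:
    def test_close_to_rest_fraction(self, params):
        """sst deviates from s0 by less than a thousandth of a percent."""
        sst = steady_state_cell_fraction(params)
        assert abs(sst - params.s0) / params.s0 < 1e-5

    def test_linearization_oracle(self, params):
        """Delta s ~ -p / sigma'(s0) with sigma'(0.8) ~ 106.4."""
        sst = steady_state_cell_fraction(params)
        p_eq = params.Ln * params.pc / (params.Ln + params.Ll * sst)
        slope = solid_stress_derivative(params.s0, params)
        assert slope == pytest.approx(106.4, abs=0.2)
        assert sst - params.s0 == pytest.approx(-p_eq / slope, rel=1e-3)
        assert sst - params.s0 == pytest.approx(-3.6e-6, abs=2e-7)

    def test_perfect_drainage_limit(self, params):
        strong = params.replace(Ll=1e9)
        assert steady_state_cell_fraction(strong) \
            == pytest.approx(params.s0, abs=1e-9)


class TestCrankNicolson:
    def test_constant_field_unchanged(self, grid):
        u = np.full(grid.n, 0.7)
        out = cn_diffuse(u, 10.0, 0.01, grid, right_value=0.7)
        assert np.allclose(out, 0.7, atol=1e-13)

    def test_zero_coefficient_identity(self, grid):
        u = np.random.default_rng(0).random(grid.n)
        assert np.array_equal(cn_diffuse(u, 0.0, 0.01, grid), u)

    def test_gaussian_spread_oracle(self):
        """Far from the origin the spherical operator is locally planar:
        a narrow Gaussian gains variance 2 D dt."""
        grid = Grid(dr=0.1, n=1201, R_tumor=1.0, R_tissue=100.0)
        r = grid.r
        r0, w0, D = 60.0, 2.0, 5.0
        u = np.exp(-((r - r0) ** 2) / (2 * w0**2))
        n_steps, dt = 100, 0.01
        for _ in range(n_steps):
            u = cn_diffuse(u, D, dt, grid)
        # moments in the planar frame, weighted by the r^2-free measure
        w = u * r * r
        mean = (w * r).sum() / w.sum()
        var = (w * (r - mean) ** 2).sum() / w.sum()
        expected = w0**2 + 2 * D * n_steps * dt
        assert var == pytest.approx(expected, rel=0.01)

    def test_dirichlet_boundary_held(self, grid):
        u = np.zeros(grid.n)
        out = cn_diffuse(u, 50.0, 0.1, grid, right_value=0.9)
        assert out[-1] == pytest.approx(0.9)

    def test_batch_matches_loop(self, grid):
        rng = np.random.default_rng(1)
        batch = rng.random((3, grid.n))
        together = cn_diffuse(batch, 7.0, 0.02, grid, right_value=0.5)
        for k in range(3):
            single = cn_diffuse(batch[k], 7.0, 0.02, grid, right_value=0.5)
            assert np.allclose(together[k], single, atol=1e-14)


class TestFluxCorrectedTransport:
    def test_zero_velocity_identity(self, grid):
        q = np.random.default_rng(2).random(grid.n)
        out = fct_advect(q, np.zeros(grid.n), 0.01, grid)
        assert np.allclose(out, q, atol=1e-15)

    def test_mass_conservation_zero_boundary_flux(self, grid):
        """Total content conserved to near machine precision."""
        r = grid.r
        q = np.exp(-((r - 20.0) ** 2) / 8.0)
        vel = 0.5 * np.sin(np.pi * r / r[-1]) ** 2
        vel[-1] = 0.0                      # no outer outflow
        total0 = (q * grid.volume).sum()
        for _ in range(50):
            q = fct_advect(q, vel, 0.01, grid)
        total = (q * grid.volume).sum()
        assert abs(total - total0) / total0 < 1e-12

    def test_no_new_extrema(self, grid):
        """FCT creates no overshoots: the maximum never grows, values stay
        nonnegative, and the minimum drops no faster than the geometric
        dilution of the diverging radial flow allows."""
        rng = np.random.default_rng(3)
        q = np.where((grid.r > 30) & (grid.r < 50), 1.0, 0.0)
        q += 0.01 * rng.random(grid.n)
        v0, dt = 0.8, 0.005
        vel = np.full(grid.n, v0)
        lo, hi = q.min(), q.max()
        r_min = grid.dr                 # worst-case dilution rate 2 v / r
        for k in range(1, 101):
            q = fct_advect(q, vel, dt, grid)
            dilution = np.exp(-2.0 * v0 * dt * k / r_min)
            assert q.max() <= hi + 1e-12
            assert q.min() >= lo * dilution - 1e-12
            assert q.min() >= -1e-15

    def test_sharper_than_upwind(self, grid):
        """Square pulse at large r: FCT beats donor-cell upwind in L1."""
        r = grid.r
        q0 = np.where((r > 30) & (r < 40), 1.0, 0.0)
        vel = np.full(grid.n, 1.0)
        dt, n_steps = 0.02, 250        # translate by 5 length units
        q_fct = q0.copy()
        q_up = q0.copy()
        for _ in range(n_steps):
            q_fct = fct_advect(q_fct, vel, dt, grid)
            q_up = _upwind(q_up, vel, dt, grid)
        exact = np.where((r > 35) & (r < 45), 1.0, 0.0)
        err_fct = np.abs(q_fct - exact).sum()
        err_up = np.abs(q_up - exact).sum()
        assert err_fct < err_up

    def test_cfl_violation_rejected(self, grid):
        q = np.ones(grid.n)
        with pytest.raises(FloatingPointError):
            fct_advect(q, np.full(grid.n, 100.0), 0.01, grid)


def _upwind(q, vel, dt, grid):
    """Plain donor-cell upwind reference used as the accuracy baseline."""
    n = grid.n
    vf = np.empty(n + 1)
    vf[0] = 0.0
    vf[1:n] = 0.5 * (vel[:-1] + vel[1:])
    vf[n] = vel[-1]
    q_up = np.where(vf[1:n] > 0, q[:-1], q[1:])
    F = np.empty(n + 1)
    F[0] = 0.0
    F[1:n] = grid.face_area[1:n] * vf[1:n] * q_up
    F[n] = grid.face_area[n] * vf[n] * q[-1]
    return q - dt * np.diff(F) / grid.volume


class TestFloatingBoundaries:
    def test_static_fields_leave_fronts_alone(self, params):
        state, grid = initialize(params)
        R_t, R_n = grid.R_tumor, grid.R_tissue
        update_floating_boundaries(state, grid, 5e-3)
        assert grid.R_tumor == pytest.approx(R_t, abs=1e-9)
        assert grid.R_tissue == pytest.approx(R_n, abs=1e-9)

    def test_front_radius_tracks_material_volume(self, params):
        state, grid = initialize(params)
        # move 30% of the tumor interface cell's content one cell out, as
        # numerical smearing would; tracking must restore it and keep the
        # front radius consistent with the conserved volume
        j = grid.cell_containing(grid.R_tumor)
        total0 = (state.n_p * grid.volume).sum()
        moved = 0.3 * state.n_p[j]
        state.n_p[j] -= moved
        state.n_p[j + 2] = moved * grid.volume[j] / grid.volume[j + 2]
        update_floating_boundaries(state, grid, 5e-3)
        assert state.n_p[j + 2] == 0.0
        assert (state.n_p * grid.volume).sum() == pytest.approx(total0)
        expected_R = np.cbrt(3 * total0 / state.n_p[0])
        assert grid.R_tumor == pytest.approx(expected_R, rel=1e-6)

    def test_front_advances_when_interface_cell_fills(self, params):
        state, grid = initialize(params)
        j = grid.cell_containing(grid.R_tumor)
        state.n_p[j] = state.n_p[j - 1] * 1.2      # overfilled interface
        update_floating_boundaries(state, grid, 5e-3)
        assert grid.cell_containing(grid.R_tumor) == j + 1
        assert state.n_p[j] == pytest.approx(state.n_p[j - 1])


class TestAdvance:
    def test_zero_dt_is_identity(self, params):
        state, grid = initialize(params)
        before = state.copy()
        advance(state, grid, params, 0.0)
        assert np.array_equal(state.n_p, before.n_p)
        assert state.t == before.t

    def test_normal_tissue_fixed_point_short(self, params):
        """A tumor-free tissue at its steady state stays put (12 h)."""
        state, grid = initialize(params, R0T=0.0, steady_glucose=True)
        ref = state.copy()
        for _ in range(240):
            advance(state, grid, params, 5e-2)
        for name in State.TISSUE_FIELDS:
            drift = np.abs(getattr(state, name) - getattr(ref, name)).max()
            assert drift < 1e-9, name
        assert grid.R_tissue == pytest.approx(40.0, abs=1e-8)

    def test_saturation_identity_and_positivity(self, params):
        state, grid = initialize(params)
        for _ in range(200):
            advance(state, grid, params, 5e-3)
        assert np.abs(state.s + state.f - 1.0).max() < 1e-15
        for name in State.TISSUE_FIELDS:
            assert getattr(state, name).min() >= -1e-12, name
        assert state.g.max() <= 1.0 + 1e-12

    def test_step_halving_consistency(self, params):
        """Two half steps agree with one full step to first order."""
        state1, grid1 = initialize(params)
        state2, grid2 = initialize(params)
        for _ in range(20):
            advance(state1, grid1, params, 4e-3)
        for _ in range(40):
            advance(state2, grid2, params, 2e-3)
        diff = np.abs(state1.n_p - state2.n_p).max()
        assert diff < 1e-4


class TestRunSimulation:
    def test_zero_horizon_returns_initial_state(self, params):
        traj = run_simulation(params, None, t_end=0.0, dt=5e-3)
        assert len(traj.times) == 1
        assert traj.records[0]["R_tumor"] == pytest.approx(2.0)

    def test_trajectory_frame_columns(self, params):
        traj = run_simulation(params, None, t_end=2.0, dt=5e-3,
                              output_every=1.0)
        frame = traj.to_frame()
        for col in ("t", "R_tumor", "R_tissue", "tumor_cell_volume",
                    "pdf", "bound_active"):
            assert col in frame.columns
        assert np.all(np.diff(frame.t.to_numpy()) > 0)

    def test_checkpoint_roundtrip_bit_compatible(self, params, tmp_path):
        traj = run_simulation(params, None, t_end=1.0, dt=5e-3)
        state, grid = traj.final_state, traj.final_grid
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, state, grid)
        restored, rgrid = load_checkpoint(path)
        # continue both for another hour and compare bit-for-bit
        t1 = run_simulation(params, None, t_end=2.0, state=state, grid=grid,
                            dt=5e-3)
        t2 = run_simulation(params, None, t_end=2.0, state=restored,
                            grid=rgrid, dt=5e-3)
        assert np.array_equal(t1.final_state.n_p, t2.final_state.n_p)
        assert np.array_equal(t1.final_state.g, t2.final_state.g)
        assert t1.final_grid.R_tumor == t2.final_grid.R_tumor

    def test_irradiation_event_damages_cells(self, params):
        schedule = TreatmentSchedule(t_irr=1.0, dose=2.0)
        traj = run_simulation(params, schedule, t_end=2.0, dt=5e-3,
                              output_every=0.5)
        frame = traj.to_frame()
        state = traj.final_state
        assert state.m.max() > 0.0
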