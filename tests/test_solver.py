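"""Flow solver: Poiseuille benchmark, conservation, linearity, convergence."""

import numpy as np
import pytest

from trabflow import (
    FluidProperties,
    GapGeometry,
    PressureBC,
    SolverSettings,
    generate_mesh,
    mass_flux,
    mesh_convergence_study,
    plane_poiseuille_wss,
    solve_flow,
)
from trabflow.wall_shear import compute_wss, peak_fss, sample_profile


def mid_channel_fss(sol, mesh, lo=450.0, hi=1050.0):
    wss = compute_wss(sol, mesh, {"bottom_wall"})
    prof = sample_profile(wss, n_samples=200)
    sel = (prof.x_um > lo) & (prof.x_um < hi)
    return prof.values[sel]


class TestPoiseuilleBenchmark:
    def test_wall_shear_matches_closed_form(self, poiseuille_solution, plain_mesh):
        mid = mid_channel_fss(poiseuille_solution, plain_mesh)
        tau = plane_poiseuille_wss(300.0, 1.5e-3, 1e-4)
        assert mid.mean() == pytest.approx(tau, rel=0.01)
        assert mid.std() / mid.mean() < 0.02  # flat plateau

    def test_flow_rate_matches_closed_form(self, poiseuille_solution):
        q = abs(mass_flux(poiseuille_solution, "inlet"))
        q_exact = (1e-4) ** 3 * 300.0 / (12 * 1e-3 * 1.5e-3)
        assert q == pytest.approx(q_exact, rel=0.01)

    def test_mass_conservation(self, poiseuille_solution, groove_solution):
        for sol in (poiseuille_solution, groove_solution):
            qin = mass_flux(sol, "inlet")
            qout = mass_flux(sol, "outlet")
            assert abs(qin + qout) / abs(qin) < 1e-6

    def test_no_slip_on_walls(self, poiseuille_solution):
        space = poiseuille_solution.space
        wall_nodes = space.boundary_q2_nodes(["top_wall", "bottom_wall"])
        vmax = np.abs(poiseuille_solution.velocity).max()
        wall_v = np.abs(poiseuille_solution.velocity[wall_nodes]).max()
        assert wall_v < 1e-12 * vmax

    def test_reynolds_number_reported(self, poiseuille_solution):
        # U_mean = H^2 dP / (12 mu L) = 1/6 m/s -> Re = 1000*U*1e-4/1e-3
        assert poiseuille_solution.reynolds == pytest.approx(16.67, rel=0.01)


class TestLinearityAndDegenerate:
    def test_zero_pressure_difference_zero_flow(self, plain_mesh):
        sol = solve_flow(plain_mesh, FluidProperties(), PressureBC(0.0, 0.0),
                         SolverSettings())
        assert sol.converged
        assert np.abs(sol.velocity).max() < 1e-20
        assert np.ptp(sol.pressure) < 1e-10

    def test_stokes_linearity_in_delta_p(self, plain_mesh):
        s = SolverSettings(model="stokes")
        sol1 = solve_flow(plain_mesh, FluidProperties(), PressureBC(150.0, 0.0), s)
        sol2 = solve_flow(plain_mesh, FluidProperties(), PressureBC(300.0, 0.0), s)
        scale = np.abs(sol1.velocity).max()
        assert np.abs(sol2.velocity - 2.0 * sol1.velocity).max() < 1e-8 * scale

    def test_navier_stokes_approaches_stokes_at_low_re(self, plain_mesh):
        bc = PressureBC(1.0, 0.0)  # Re ~ 0.06
        ns = solve_flow(plain_mesh, FluidProperties(), bc, SolverSettings())
        st = solve_flow(plain_mesh, FluidProperties(), bc, SolverSettings(model="stokes"))
        assert ns.reynolds < 0.1
        diff = np.abs(ns.velocity - st.velocity).max()
        assert diff < 0.01 * np.abs(st.velocity).max()

    def test_converged_flag_and_history(self, groove_solution):
        assert groove_solution.converged
        assert groove_solution.residual_history[-1] <= 1e-8

    def test_nonconvergence_is_reported_not_hidden(self, groove_mesh):
        """A hopeless iteration budget yields converged=False with history."""
        s = SolverSettings(newton_max_iter=1, newton_tol=1e-14)
        sol = solve_flow(groove_mesh, FluidProperties(), PressureBC(300.0, 0.0), s)
        assert not sol.converged
        assert len(sol.residual_history) > 0


class TestSymmetryAndProfile:
    def test_centered_crack_profile_symmetric(self, groove_solution, groove_mesh):
        wss = compute_wss(groove_solution, groove_mesh)
        prof = sample_profile(wss, n_samples=200)
        v = prof.values
        # compare against the x -> L-x mirror away from the ends
        vm = v[::-1]
        sel = (prof.x_um > 150) & (prof.x_um < 1350) & (v > 1.0) & (vm > 1.0)
        rel = np.abs(v[sel] - vm[sel]) / np.abs(v[sel])
        assert np.median(rel) < 0.02

    def test_total_pressure_inlet_reduces_flow(self, plain_mesh):
        """Stagnation-pressure driving loses the dynamic head to inertia."""
        static = solve_flow(plain_mesh, FluidProperties(), PressureBC(300.0, 0.0),
                            SolverSettings())
        total = solve_flow(plain_mesh, FluidProperties(),
                           PressureBC(300.0, 0.0, inlet_type="total"),
                           SolverSettings())
        assert total.converged
        assert abs(mass_flux(total, "inlet")) < abs(mass_flux(static, "inlet"))


class TestMeshConvergence:
    def test_plain_channel_peak_converges(self, plain_geom):
        df = mesh_convergence_study(
            plain_geom, FluidProperties(), PressureBC(300.0, 0.0),
            [20.0, 10.0, 5.0], SolverSettings())
        changes = df["rel_change"].dropna().to_numpy()
        # successive changes shrink (up to round-off when already exact)
        assert changes[-1] <= changes[0] + 1e-9
        assert df.attrs["converged"]
        assert df["rel_change"].iloc[-1] < 0.02

    def test_requires_three_strictly_decreasing_sizes(self, plain_geom):
        args = (plain_geom, FluidProperties(), PressureBC(300.0, 0.0))
        with pytest.raises(ValueError):
            mesh_convergence_study(*args, [20.0, 10.0])
        with pytest.raises(ValueError):
            mesh_convergence_study(*args, [20.0, 20.0, 10.0])


class TestSettingsValidation:
    @pytest.mark.parametrize("kwargs", [
        {"model": "euler"},
        {"newton_tol": 2.0},
        {"continuation_steps": 0},
        {"stabilization": "sometimes"},
        {"open_boundary": "periodic"},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverSettings(**kwargs)

    def test_backward_flow_bc_rejected(self):
        with pytest.raises(ValueError):
            PressureBC(0.0, 100.0)

    def test_nonpositive_fluid_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(density=-1.0)
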