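"""WSS extraction, profiles, peaks, gradients, shape classification."""

import numpy as np
import pytest

from trabflow import (
    FluidProperties,
    PressureBC,
    SolverSettings,
    WSSProfile,
    compute_wss,
    crack_gradient,
    peak_fss,
    profile_summary,
    sample_profile,
)
from trabflow.solver import FlowSolution
from trabflow._fem import get_space


def synthetic_solution(mesh, velocity_fn):
    """FlowSolution whose Q2 velocity field is prescribed analytically."""
    space = get_space(mesh)
    U = np.array([velocity_fn(p) for p in space.q2_coords])
    return FlowSolution(
        mesh=mesh, velocity=U, pressure=np.zeros(space.n_p), converged=True,
        residual_history=[0.0], reynolds=0.0, settings=SolverSettings(),
        props=FluidProperties(), bc=PressureBC(0.0, 0.0),
    )


class TestComputeWss:
    def test_uniform_shear_flow(self, plain_mesh):
        """u = (γ z, 0) with γ = 100 1/s and μ = 1e-3 gives 0.1 Pa on z=0."""
        sol = synthetic_solution(plain_mesh, lambda p: [100.0 * p[1], 0.0])
        field = compute_wss(sol, plain_mesh, {"bottom_wall"})
        assert np.allclose(field.values, 0.1, rtol=1e-10)

    def test_zero_velocity_zero_wss(self, plain_mesh):
        sol = synthetic_solution(plain_mesh, lambda p: [0.0, 0.0])
        field = compute_wss(sol, plain_mesh, {"bottom_wall", "top_wall"})
        assert np.all(field.values == 0.0)

    def test_normal_component_excluded(self, plain_mesh):
        """A pure normal-gradient field u = (0, a z) exerts no wall shear."""
        sol = synthetic_solution(plain_mesh, lambda p: [0.0, 50.0 * p[1]])
        field = compute_wss(sol, plain_mesh, {"bottom_wall"})
        assert np.abs(field.values).max() < 1e-12

    def test_poiseuille_reference_value(self, poiseuille_solution, plain_mesh):
        field = compute_wss(poiseuille_solution, plain_mesh, {"bottom_wall"})
        prof = sample_profile(field, n_samples=100)
        mid = prof.values[(prof.x_um > 450) & (prof.x_um < 1050)]
        assert mid.mean() == pytest.approx(10.0, rel=0.01)

    def test_wss_nonnegative(self, groove_solution, groove_mesh):
        field = compute_wss(groove_solution, groove_mesh)
        assert (field.values >= 0.0).all()

    def test_unknown_tag_raises(self, poiseuille_solution, plain_mesh):
        with pytest.raises(KeyError):
            compute_wss(poiseuille_solution, plain_mesh, {"moon_wall"})


class TestSampleProfileAndPeak:
    def test_constant_field_constant_profile(self, plain_mesh):
        sol = synthetic_solution(plain_mesh, lambda p: [100.0 * p[1], 0.0])
        field = compute_wss(sol, plain_mesh, {"bottom_wall"})
        prof = sample_profile(field, n_samples=50)
        assert np.allclose(prof.values, 0.1, rtol=1e-10)
        assert np.all(np.diff(prof.x_um) > 0)

    def test_crack_mouth_takes_floor_value(self, groove_solution, groove_mesh):
        field = compute_wss(groove_solution, groove_mesh)
        prof = sample_profile(field, n_samples=300)
        in_crack = (prof.x_um > 730) & (prof.x_um < 770)
        assert prof.values[in_crack].max() < 0.1  # near-stagnant groove floor

    def test_min_samples_enforced(self, groove_solution, groove_mesh):
        field = compute_wss(groove_solution, groove_mesh)
        with pytest.raises(ValueError):
            sample_profile(field, n_samples=8)

    def test_peak_is_maximum(self):
        prof = WSSProfile(x_um=np.array([1.0, 2.0, 3.0]),
                          values=np.array([1.0, 5.0, 3.0]))
        assert peak_fss(prof) == 5.0
        const = WSSProfile(x_um=np.array([1.0, 2.0]), values=np.array([2.5, 2.5]))
        assert peak_fss(const) == 2.5

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            WSSProfile(x_um=np.array([2.0, 1.0]), values=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            WSSProfile(x_um=np.array([1.0]), values=np.array([1.0, 2.0]))


class TestCrackGradient:
    def test_constant_field_zero_gradient(self, groove_solution, groove_mesh):
        field = compute_wss(groove_solution, groove_mesh)
        field.values = np.full_like(field.values, 2.0)
        g = crack_gradient(field)
        assert np.abs(g.gradient_pa_per_mm).max() < 1e-10

    def test_linear_field_recovers_slope(self, groove_solution, groove_mesh):
        """FSS linear in arc length with slope 0.2 Pa/mm."""
        field = compute_wss(groove_solution, groove_mesh)
        crack = field.tags == "crack_wall"
        cen = field.centroids / 1e-6
        x, z = cen[:, 0], cen[:, -1]
        d, w, xl = 100.0, 50.0, 725.0
        s = np.where(field.normals[:, 0] < -0.5, -z,
                     np.where(field.normals[:, -1] < -0.5, d + (x - xl),
                              2 * d + w + z))
        field.values = np.where(crack, 0.2 * (s * 1e-3), field.values)
        g = crack_gradient(field)
        assert np.allclose(g.gradient_pa_per_mm, 0.2, rtol=1e-6)

    def test_gradient_arc_covers_full_perimeter(self, groove_solution, groove_mesh):
        g = crack_gradient(compute_wss(groove_solution, groove_mesh))
        assert g.arc_mm.min() >= 0.0
        assert g.arc_mm.max() <= (2 * 100.0 + 50.0) * 1e-3
        assert set(g.region) == {"upstream_wall", "floor", "downstream_wall"}

    def test_no_crack_raises(self, poiseuille_solution, plain_mesh):
        field = compute_wss(poiseuille_solution, plain_mesh, {"bottom_wall"})
        with pytest.raises(ValueError):
            crack_gradient(field)


class TestProfileSummary:
    def test_inverted_u_classification(self):
        x = np.linspace(5.0, 1495.0, 150)
        v = np.clip(np.minimum(x, 1500.0 - x) / 300.0, None, 1.0) * 10.0
        summ = profile_summary(WSSProfile(x_um=x, values=v))
        assert summ["shape"] == "inverted_U"

    def test_flat_classification(self):
        x = np.linspace(5.0, 1495.0, 100)
        summ = profile_summary(WSSProfile(x_um=x, values=np.full(100, 4.0)))
        assert summ["shape"] == "flat"
        assert summ["fraction_above_threshold"] == 1.0

    def test_monotone_profile_is_other(self):
        x = np.linspace(5.0, 1495.0, 100)
        summ = profile_summary(WSSProfile(x_um=x, values=np.linspace(0, 10, 100)))
        assert summ["shape"] == "other"

    def test_threshold_fraction(self):
        x = np.linspace(0.5, 99.5, 100)
        v = np.linspace(0.0, 9.9, 100)
        summ = profile_summary(WSSProfile(x_um=x, values=v), threshold=3.0)
        assert summ["fraction_above_threshold"] == pytest.approx(0.69, abs=0.02)
        assert summ["median"] == pytest.approx(np.median(v))
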