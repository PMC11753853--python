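import numpy as np
import pytest

from trabflow import (
    FluidProperties,
    GapGeometry,
    MicrocrackSpec,
    PressureBC,
    SolverSettings,
    generate_mesh,
    solve_flow,
)

LARGE_GROOVE = MicrocrackSpec(depth_um=100.0, width_um=50.0)


@pytest.fixture(scope="session")
def plain_geom():
    return GapGeometry(length_um=1500.0, width_um=100.0, height_um=100.0, crack=None)


@pytest.fixture(scope="session")
def groove_geom():
    return GapGeometry(length_um=1500.0, width_um=100.0, height_um=100.0,
                       crack=LARGE_GROOVE)


@pytest.fixture(scope="session")
def plain_mesh(plain_geom):
    return generate_mesh(plain_geom, 10.0)


@pytest.fixture(scope="session")
def groove_mesh(groove_geom):
    return generate_mesh(groove_geom, 10.0, 0.25)


@pytest.fixture(scope="session")
def poiseuille_solution(plain_mesh):
    """Stokes solve of the reference plane-channel case (ΔP = 300 Pa)."""
    return solve_flow(plain_mesh, FluidProperties(), PressureBC(300.0, 0.0),
                      SolverSettings(model="stokes"))


@pytest.fixture(scope="session")
def groove_solution(groove_mesh):
    """Navier–Stokes solve of the large-groove reference case."""
    return solve_flow(groove_mesh, FluidProperties(), PressureBC(300.0, 0.0),
                      SolverSettings())
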