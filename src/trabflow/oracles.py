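"""Closed-form and series solutions used as independent solver checks.

Pure functions of the flow parameters — deliberately independent of the
mesh and solver modules, so agreement with the FEM solution is a genuine
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DuctSpec",
    "plane_poiseuille_wss",
    "rect_duct_solution",
    "reynolds_number",
]


@dataclass(frozen=True)
class DuctSpec:
    """Rectangular duct cross-section driven by a constant pressure gradient.

    ``pressure_gradient`` is −dp/dx > 0 for forward flow, Pa/m.
    """

    height_um: float
    width_um: float
    pressure_gradient: float
    viscosity: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("height_um", "width_um", "pressure_gradient", "viscosity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def plane_poiseuille_wss(delta_p: float, length: float, height: float,
                         viscosity: float = 1e-3) -> float:
    """Wall shear stress of fully developed plane Poiseuille flow: H·ΔP/(2L).

    Arguments in SI (Pa, m, Pa·s); ΔP = 0 gives 0.  The viscosity cancels
    in the wall stress but is validated for interface symmetry with the
    other oracles.
    """
    if length <= 0 or height <= 0 or viscosity <= 0 or delta_p < 0:
        raise ValueError("length, height, viscosity must be positive; delta_p >= 0")
    return height * delta_p / (2.0 * length)


def rect_duct_solution(spec: DuctSpec, n_terms: int = 100) -> dict:
    """Fourier-series Poiseuille flow in a rectangular duct.

    For a duct with height H (z ∈ [0, H]) and width W (y ∈ [−W/2, W/2]),

        u(y,z) = (G/2μ) z(H−z)
                 − (4GH²/μπ³) Σ_{n odd} cosh(nπy/H) sin(nπz/H)
                                        / (n³ cosh(nπW/2H))

    with G = −dp/dx.  Returns the mean velocity, the bottom-wall shear at
    the width centerline, the flow rate, and a truncation estimate (the
    magnitude of the last term kept in the shear series).
    """
    if n_terms < 10:
        raise ValueError("n_terms must be >= 10")
    H = spec.height_um * 1e-6
    W = spec.width_um * 1e-6
    G = spec.pressure_gradient
    mu = spec.viscosity
    n = np.arange(1, 2 * n_terms, 2, dtype=float)      # odd terms
    beta = n * np.pi * W / (2.0 * H)
    # overflow-safe 1/cosh for wide ducts
    sech = 2.0 * np.exp(-beta) / (1.0 + np.exp(-2.0 * beta))
    # centerline (y=0) bottom-wall shear: μ ∂u/∂z at z=0
    shear_terms = (4.0 * G * H / np.pi ** 2) * sech / n ** 2
    wall_shear = G * H / 2.0 - shear_terms.sum()
    # flow rate: Q = GWH³/12μ − (16GH⁴/μπ⁵) Σ tanh(β)/n⁵
    q_terms = (16.0 * G * H ** 4 / (mu * np.pi ** 5)) * np.tanh(beta) / n ** 5
    flow_rate = G * W * H ** 3 / (12.0 * mu) - q_terms.sum()
    return {
        "mean_velocity": flow_rate / (W * H),
        "wall_shear_center": wall_shear,
        "flow_rate": flow_rate,
        "truncation": abs(shear_terms[-1]),
    }


def reynolds_number(density: float, mean_velocity: float, height: float,
                    viscosity: float = 1e-3) -> float:
    """Re = ρ·U·H/μ, the laminar-assumption audit quantity."""
    if density <= 0 or height <= 0 or viscosity <= 0 or mean_velocity < 0:
        raise ValueError("inputs must be positive (velocity non-negative)")
    return density * mean_velocity * height / viscosity
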