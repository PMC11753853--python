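# Methods

`trabflow` computes the steady laminar flow of interstitial fluid through a
simplified inter-trabecular gap containing a rectangular microcrack, and the
wall shear stress (FSS) that flow exerts on the trabecular surfaces.  This
note records the model, its numerical treatment, the measurement protocols,
and the choices made where the problem left the design open.

## Model

The gap between two trabecular surfaces is idealized as a box: length
L = 1500 μm along the flow axis x, width W along y, height H along z.  Bone
microdamage is a rectangular groove in the bottom wall, depth d below z = 0
and width w along x, centered at x = L/2 by default and spanning the full
width in 3D (so planar 2D and full 3D models are nested).  The interstitial
fluid is treated as water at room temperature, ρ = 1000 kg/m³ and
μ = 10⁻³ Pa·s, with steady incompressible laminar flow:

    ρ (u·∇)u = −∇p + μ Δu,   ∇·u = 0,

no-slip on every wall, and a pressure difference driving the flow through
the open ends.  The Stokes limit (dropping inertia) is available as a model
option and doubles as a linearity oracle.  FSS on a wall is the magnitude of
the tangential part of the viscous traction μ(∇u + ∇uᵀ)·n.

### Open-boundary treatment

How "a pressure at the inlet" acts is the single most consequential modeling
choice, and the package exposes the alternatives explicitly:

* `open_boundary="normal_flow"` (default): the gradient-form pseudo-traction
  μ ∂u/∂n − p n is set to −p_bc n with the tangential velocity constrained
  to zero.  Fully developed flow then satisfies the boundary condition
  exactly: the plane-Poiseuille solution with wall shear τ = H·ΔP/(2L) is
  reproduced to solver precision, which is what makes the closed-form
  oracles sharp.
* `open_boundary="no_viscous_stress"`: the full traction
  μ(∇u+∇uᵀ)·n − p n is prescribed, i.e. zero tangential viscous stress on
  the end planes.  Wall shear then dips toward zero at the ends and
  recovers over a distance of order H.
* `inlet_type="total"` on the pressure BC interprets the inlet value as
  stagnation pressure p₀ = p + ½ρ|u|².  For small Reynolds numbers this is
  indistinguishable from a static pressure; for tall gaps it limits the
  flow to the Bernoulli velocity √(2p₀/ρ) and changes the answer
  qualitatively (see "Tall gaps" below).

An important consequence of the traction-type conditions: a unidirectional
channel flow has identically zero convective acceleration, so plane
Poiseuille is an *exact* steady Navier–Stokes solution at any Reynolds
number.  Under the static default the tall-gap cases therefore converge to
the developed profile even at nominal Re ~ 10⁴; the reported Reynolds
number flags these cases for interpretation.

## Discretization

Because the domain is a union of axis-aligned boxes, meshes are structured
tensor-product grids (quadrilaterals in 2D, hexahedra in 3D) with grid lines
snapped to the crack edges; cells in the crack band are refined by
`refine_crack_factor` (default 0.25 — the in-crack gradient needs resolution
finer than the groove width).  Every boundary facet carries exactly one tag
(inlet, outlet, top/bottom wall, crack wall, side walls); the tag partition
is closed by construction and tested against exact perimeter/area formulas.

Velocity and pressure use the Taylor–Hood Q2/Q1 pairing, which satisfies the
inf-sup condition, so no pressure stabilization is needed and discrete mass
conservation holds to linear-solver precision (the inlet/outlet flux balance
is checked to 10⁻⁶ relative, and measures ~10⁻¹⁵ in practice).  A quadratic
velocity space also represents the parabolic channel profile exactly, which
is why the Poiseuille oracle passes at 0.01% rather than at a
discretization-limited tolerance.

The nonlinear system is solved by Newton iteration (relative residual
tolerance 10⁻⁸, at most 25 iterations) started from the Stokes solution,
with adaptive continuation in the pressure load: if Newton fails to
contract, the load step is bisected from the last converged state.  In
convection-dominated cells (cell Péclet > 1) a streamline (SUPG) term
stabilizes the advective operator; it is assembled Picard-style (the
stabilization's own linearization is frozen), which costs Newton its
quadratic tail but not its robustness.  Non-convergence is always reported
(`converged=False` with the residual history), never hidden; sweep rows
that fail are flagged with a NaN peak and excluded from regressions only
with an explicit warning.

Linear systems are solved with SuperLU on the assembled saddle-point
Jacobian.  All internal arithmetic is SI; μm and Pa appear only at the
configuration surface, converted exactly once.

## Measurement protocols

**FSS profiles** are read on the bottom wall along x (at the y-centerline
in 3D) by nearest-facet sampling at uniform positions; over the groove
mouth the profile takes the crack-floor value, producing the characteristic
low-FSS dip at the microcrack.

**Peak gap FSS** (the response variable of every parametric study) is read
on the *fully developed upstream plateau*: after the first 10% of the
channel (inlet development) and more than 1.5 H before the crack mouth.
Three discrete effects are thereby excluded deliberately:

1. the stress at the facets touching the 270° crack-mouth corners, which is
   a corner singularity of the rectangular idealization — it grows without
   bound under mesh refinement (measured +10–40% over the plateau at
   practical resolutions) and is therefore not a convergent quantity;
2. the convective wake downstream of the groove, whose recovery length
   grows with Re and would bias ratios between cases run at different
   Reynolds numbers;
3. inlet/outlet end effects (elevations under `normal_flow`, dips under
   `no_viscous_stress`).

With this protocol the plateau peak is mesh-stable to < 0.5% across the
resolutions used.  Tall gaps, where no upstream window exists, fall back to
the interior maximum outside a 300 μm zone around the crack.
`peak_fss()` itself remains the plain profile maximum.

**In-crack gradients** are centered finite differences of FSS magnitude
with respect to arc length along the groove boundary — down the upstream
wall, across the floor, up the downstream wall — reported in Pa/mm (the
only scale on which the published 0–0.4 Pa/mm range is dimensionally
sensible).

**Profile shape** is classified `inverted_U` when the first and last
deciles' means are each below 80% of the central plateau level (the median
over the central half, robust to the crack dip), `flat` when the overall
coefficient of variation is under 2%, else `other`.

## The parametric studies and their fixed parameters

The studies fix parameters the source description leaves open; the choices
are:

| study | varied | fixed |
|---|---|---|
| pressure | ΔP ∈ {50, 100, 200, 250} Pa | 2D, H = 100 μm, large groove (d = 100, w = 50 μm), outlet 0 Pa |
| width | W ∈ {1000 … 100} μm (3D) | H = 100 μm, inlet 300 Pa static, outlet 0, large groove full-width |
| height | H ∈ {100, 200, 500, 1000} μm | 2D, inlet 300 Pa static, outlet 0, large groove |
| crack depth / width | {100, 50, 20, 10} μm | 2D, H = 100 μm, inlet 300 Pa, other crack dimension at its large-groove value |

Both printed readings of the small groove ship as presets
(`small_groove_table1`: d = 20, w = 10 μm; `small_groove_s34`: d = 10,
w = 20 μm); the gradient study uses the d = 10 / w = 20 reading alongside
the large groove.

**Problem sizes.**  The default 2D target element size is 10 μm (×0.25 in
the crack band), giving ~2,400–7,200 cells per case.  The 3D width study
uses anisotropic coarse meshes: 75 μm along x (×0.25 at the crack), W/8
across the width, and H/4 across the height for wide gaps (W ≥ 2H, where
the z-profile is quasi-parabolic and exactly representable by Q2) or H/8
for narrow ones — validated at 0.4% against the rectangular-duct series on
a plain 3D channel.  Tall 2D gaps use at least 40 cells across H.  These
sizes are far below the ~200k-element meshes a commercial solver would use,
and were chosen so that the full reproduction runs on a single CPU in
minutes; the mesh-convergence study utility documents the residual
discretization error (< 2% between the two finest meshes on the reference
scenario).

## Verification

* Plane Poiseuille: mid-channel bottom-wall FSS within 1% of H·ΔP/(2L)
  (measured 0.01%); volumetric flux within 1% of H³ΔP/(12μL).
* Rectangular duct: 3D plain-channel centerline wall shear and mean
  velocity within 3% of the Fourier-series solution (measured 0.4%); the
  series itself is verified against the plane limit, the square-duct
  retardation factor 0.675, and the textbook wide-duct flow deficit
  1 − 0.63·H/W.
* Conservation, Stokes linearity in ΔP (exact to 10⁻⁸), Navier–Stokes →
  Stokes as Re → 0, mirror symmetry of the centered-crack profile, and
  no-slip to 10⁻¹² are asserted as properties.
* The oracles are pure functions with no dependence on mesh or solver
  modules, so agreement is a genuine cross-check.

## Known limitations and discrepancies with the published numbers

* **Tall-gap magnitude vs. height linearity.**  Under the static reading of
  the boundary pressures the H = 1000 μm case develops fully
  (peak ≈ H·ΔP/2L ≈ 100 Pa, R² of peak-vs-H ≈ 1.0); under the
  total-pressure reading the flow is inertia-limited (interior plateaus
  ~10–19 Pa, close to the published ≈15 Pa, but saturating in H so the
  linear R² collapses to ~0.6).  No single reading reproduces both
  published height-study numbers; the package defaults to the static
  reading (which its other published values validate at H = 100 μm) and
  ships the total-pressure variant as a first-class option.
* **In-crack gradient range.**  Resolving the groove's shear-driven
  recirculation yields near-mouth wall FSS of order 1–10 Pa decaying over
  ~w/2π ≈ 8 μm, i.e. gradients of order 10²–10³ Pa/mm near the mouth
  corners — far above the published 0–0.4 Pa/mm envelope, which is only
  consistent with a crack interior that is numerically quiescent at coarse
  resolution.  Deep in the groove the model agrees with the published
  picture: floor FSS is ~10⁻⁵–10⁻³ Pa and the median floor gradient is
  ~0.13 Pa/mm.
* **Inverted-U profile ends.**  With traction-type pressure boundaries the
  end zones where wall shear deviates from the plateau span only ~H, so
  decile-based shape classification reports `other` rather than
  `inverted_U`; broad low-FSS end ramps like the published ones do not
  arise under any pressure boundary condition constructed here.
* The model is a rigid box: no real trabecular geometry, no fluid–structure
  interaction, no pulsatile flow, Newtonian fluid, single non-intersecting
  crack.  Biology (cell migration, remodeling) is entirely out of scope.
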