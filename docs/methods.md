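# Methods

`cardioem` simulates two-way coupled cardiac electromechanics: electrical
excitation drives mechanical contraction (excitation–contraction coupling),
and deformation feeds back on the electrics (mechanoelectric feedback)
through a stretch-activated current and a deformation-dependent conduction
tensor. This note records the model, the numerical scheme, the parameters
and their defaults, and the design choices made where the design was
genuinely open.

## Governing model

**Electrophysiology.** The transmembrane potential `v` (mV) obeys the
monodomain reaction–diffusion equation

    ∂v/∂t − ∇x·(D ∇x v) + I_ion / C_m = 0,

with membrane capacitance `C_m = 1 µF/cm²` and the total membrane current of
the eight-variable Beeler–Reuter (BR) ventricular cell model,

    I_ion = I_Na + I_K1 + I_x1 + I_Ca + I_sac − I_stim   [µA/µF],

using the standard published 1977 coefficient set (fast sodium `m, h, j`
gates, slow-inward `d, f` gates and calcium `Ca_i`, time-activated outward
`x1`). The gate named `f` in the cell model is called `f_gate` in the code to
avoid collision with the active-tension variable. The stimulus is a square
pulse of 80 µA/µF for 1 ms; it enters `I_ion` with a minus sign, so the
pulse *depolarizes* the membrane (the sign convention is configurable via
`stim_amplitude`). Spatial gradients are taken in the current (deformed)
configuration `x`.

**Mechanics.** Deformation is quasi-static (no inertia): at every time
instant the Kirchhoff stress satisfies `∇x·σ + b = 0` with `b = 0` by
default. The stress is the sum of a passive and an active part. With total
deformation gradient `F = ∂x/∂X` (accumulated from the original
configuration), left Cauchy–Green tensor `p = F Fᵀ`, unit reference fiber
`a₀`, deformed fiber `a = F a₀`, fourth pseudo-invariant `B = |a|²`,
`A = det(FᵀF)` and structural tensor `κ = a⊗a`:

    σ_pass = (χ/2 · ln A − ζ) I + ζ p + 2 δ ξ (B − 1) κ,
    σ_act  = T_a κ,

where `δ = 1` iff `|a| > 1` (tension-only fiber reinforcement) and the
identity tensor on the first term makes the reference configuration exactly
stress-free. This is a compressible neo-Hookean matrix plus a quadratic
fiber energy; the implementation is verified in the tests against central
finite differences of the underlying strain energy.

**Active tension.** `T_a` (MPa) follows the voltage-driven relaxation law

    dT_a/dt = ε(v) [ k_f (v − v_r) − T_a ],
    ε(v) = ε₀ + (ε_∞ − ε₀) exp(−exp(−l (v − v̄))),

so `T_a` relaxes toward `k_f (v − v_r)` at a rate that switches smoothly
from `ε₀` (diastole) to `ε_∞` (systole). Intracellular-calcium–driven
tension is deliberately out of scope; voltage controls tension directly.
`ε` is used as a temporal rate: although its parameters are conventionally
quoted in 1/mV, dimensional consistency of the rate equation requires 1/ms,
and the numeric values are used unchanged. `T_a` is not clamped to be
nonnegative; transient negative excursions (v below `v_r`) are retained.

**Mechanoelectric feedback.** Two channels: the conduction tensor

    D = d_iso I + d_ani κ

uses the *deformed* structural tensor, so conduction follows the fibers as
the tissue reshapes; and the stretch-activated channel current

    I_sac = δ G_s (|a| − 1)(v − v_s)

with `δ` as above — a linear conductance that engages only under stretch.

**Boundary conditions.** No-flux for `v` and traction-free for the mechanics
on the whole surface (both drop out of the weak forms); a set of pinned
nodes supplies the essential conditions that make the mechanics well posed.

## Numerical scheme

Operator splitting per PDE step `dt_pde` (default 0.1 ms):

1. **Reaction stage** — `dt_pde/dt_ode` forward-Euler substeps (default
   `dt_ode` 0.005 ms) of the cell ODEs and the tension ODE at every
   non-scar node, both using the pre-substep voltage. Gates may optionally
   use the exact exponential (Rush–Larsen) update; after each substep gates
   are clamped to [0, 1] with a 1e−6 overshoot tolerance (violations abort
   with a suggestion to reduce `dt_ode`). A hard guard aborts if
   |v| > 500 mV.
2. **PDE stage** — Galerkin discretization on trilinear hexahedra with
   2×2×2 Gauss quadrature, updated-Lagrangian: integrals and shape-function
   gradients over the current configuration (recomputed every step through
   `dNdx = dNdX F⁻¹`, `dv = det F · dV_ref`), while `F` itself is total.
   The voltage block uses implicit Euler with a consistent mass matrix; the
   mechanics block is the linearized equilibrium residual. Both are gathered
   into one sparse 4N×4N operator over the per-node unknowns
   (Δx, Δy, Δz, Δv) and solved monolithically; increments update `x` and
   `v` simultaneously.

**Tangent.** The mechanics tangent is assembled by *central* finite
differences of the element internal-force residual (step 1e−5 of the mean
element edge). Forward differences are insufficient here: the thin-tissue
stiffness spans ~6 orders of magnitude and forward-difference truncation
noise (~1e−5 relative) swamps the softest true modes, making the operator
indefinite; central differences (~1e−10) resolve them. The x–v
cross-sensitivity blocks are lagged within the step: `T_a` is frozen during
the PDE stage (it advances in the reaction stage), and the geometry
dependence of the diffusion/mass operators is evaluated at the current
iterate. With `newton_iters = 1` (default) this is the classic
single-linearization semi-implicit update; `newton_iters > 1` re-assembles
and re-solves within the step. The tests verify that 1 vs 5 iterations
differ by < 0.5 mV over a coupled run, and that halving both time steps
halves the splitting error.

**Linear solver.** Jacobi-preconditioned restarted GMRES (relative residual
1e−8) matching the reference scheme, or a sparse direct LU (`direct`) as the
documented fallback. The packaged presets default to the direct solver: on
desk-scale meshes one factorization per step is faster and, in
electrophysiology-only mode where the geometry is frozen, the operator is
factorized once and reused. A zero diagonal (no pinned nodes) raises a
well-posedness error before any solve.

**Scar.** Scar elements conduct nothing (`D = 0`) and develop no active
stress, but retain full passive stiffness; nodes entirely surrounded by scar
skip the reaction stage and their voltage rows are held (identity rows), so
scar tissue stays at the resting potential and deforms only passively.
Whether scar should also suppress `I_sac` is unstated in the source model;
since scar nodes skip the whole reaction stage, `I_sac` is suppressed there
as well.

## Parameters and defaults

| Parameter | Meaning | Default | Units |
|---|---|---|---|
| `C_m` | membrane capacitance | 1 | µF/cm² |
| `G_s`, `v_s` | stretch-channel conductance / reversal | 10, −20 | mS/µF, mV |
| stimulus | square pulse amplitude / duration | 80, 1 | µA/µF, ms |
| `χ`, `ζ` | isotropic Lamé-type moduli | 0.5, 0.2 | MPa |
| `ξ` | passive fiber stiffness | 0.1 | MPa |
| `d_iso`, `d_ani` | conductivities | 0.001, 0.0001 | cm²/ms |
| `k_f` | max tension slope | 0.005 | MPa/mV |
| `v_r` | tension resting reference | −94.7 | mV |
| `ε₀`, `ε_∞`, `l`, `v̄` | switch function | 0.1, 1, 1, 0 | /ms, /ms, /mV, mV |
| `dt_ode`, `dt_pde` | substep / PDE step | 0.005, 0.1 | ms |

A note on `v_r`: the conventional quote of −94.7 mV for the BR resting
potential is kept as the default of the tension law, but the BR model as
published actually rests at ≈ −84.6 mV (verified here both by long
relaxation and by root-finding on the steady-state equations; the package
computes and reports the value it actually produces). One consequence of
the −94.7 mV default is a small background tension `k_f·(−84.6 + 94.7) ≈
0.05 MPa` (about 10% of peak systolic tension) even in quiescent tissue;
set `v_r = -84.57` to remove it.

## Generated geometries (what they emulate, and what not)

**Thin tissue slab** — 0.4 × 0.4 × 0.001 cm, one element through the
thickness, uniform (default vertical) fibers, centered so the probe corner
is at (−0.2, −0.2) cm. The top-left and bottom-right corner node columns
are pinned. Because only two point supports on a 0.001 cm thick sheet leave
a rigid rotation about their common diagonal resisted only through the
thickness lever arm (relative stiffness ~(t/L)² ≈ 1e−5), the slab is
treated quasi-two-dimensionally: the z-component of every node is pinned as
well. The tissue is effectively 2D (as its aspect ratio 400:1 suggests);
through-thickness thickening is suppressed.

**Stimulus region** — the source experiments state only that stimulation is
"at the center". With the published 80 µA/µF × 1 ms pulse, ignition against
the diffusive load of neighboring tissue requires a patch a few elements
across: a single stimulated node column is subthreshold at every mesh size
studied. The packaged slab presets therefore stimulate a *square* center
patch of half-width 0.04 cm. A square (rather than a ball) is exactly
representable on the 0.04/0.02/0.01 cm grids, so mesh refinement changes
only the PDE discretization and not the stimulated region — without this
the mesh-consistency study measures stimulus digitization, not convergence.
Ball-shaped and ventricle base-patch regions are also available.

**Idealized half-ellipsoid ventricle** — a structured hexahedral shell
(default outer semi-axes 2.0 × 2.0 × 3.2 cm, wall 0.8 cm), base open at
z = 0 and truncated slightly above the apex: closing the apex with a
structured hex shell requires collapsed elements, which would violate the
positive-Jacobian requirement, so a small configurable apex gap is left
instead. Fibers are circumferential — exactly orthogonal to the radial
direction toward the geometric center, so fiber normals point centerward
and the fibers form layered sheets; within 5° of the apex axis, where the
rule degenerates, a fixed tangent fallback (still exactly orthogonal to the
radial direction) is used. This fiber rule is a robustness-test idealization,
not anatomy. Base-plane nodes are pinned. The optional scar is a sphere
(default radius 1 cm) centered on the outer wall at mid-height, spanning the
full wall thickness.

**Conductivity at ventricle scale.** The coarse shell mesh (~0.3–0.5 cm
edges) cannot resolve the ~0.01 cm tissue-scale wavefront, and with
`d_iso = 0.001 cm²/ms` discrete propagation blocks entirely. The ventricle
presets therefore scale the conductivities ×20 (`d_iso = 0.02`,
`d_ani = 0.002 cm²/ms`), restoring a resolvable wavefront. The scar
comparison — a visibly smaller depolarized area than the scar-free
control — is driven by the scar's zero conduction and is insensitive to this
scaling. Slab experiments use the published conductivities unchanged.

## Problem sizes used in the shipped studies

The packaged presets and tests run at sizes chosen for a single-CPU
workstation: the slab experiments use mesh 0.01 cm (40×40 elements; the
source experiments used 0.004 cm, i.e. 100×100), the mesh-consistency study
compares 0.04/0.02/0.01 cm over a 40 ms window, the coupled anisotropic run
covers 15–20 ms of systole, and the ventricle shell has ~600 elements. The
diffusion eigenmode check does run at mesh 0.004 cm (10,000 elements).

## What passing tests do and do not show

The synthetic geometries exercise every coupling path of the model —
excitation → tension → deformation → conduction/current feedback — under
controlled conditions with known symmetries and closed-form limits. They do
not emulate real myocardium: no transmural fiber rotation, no orthotropy,
no realistic anatomy, calcium dynamics deliberately excluded, quasi-static
mechanics without pericardial or fluid loads. Agreement here validates the
numerics and the implementation of the stated model, not physiological
fidelity.

## Known limitations

* Forward Euler limits `dt_ode`; the BR sodium kinetics are stable at the
  default 0.005 ms but not much beyond ~0.02 ms.
* The single-linearization step can lag a very fast tension ramp; increase
  `newton_iters` (or reduce `dt_pde`) for stiffer active-tension parameters.
* Large sustained contraction (fiber stretch ≈ 0.65) is within the
  updated-Lagrangian scheme's comfort zone on the slab, but mesh distortion
  with stronger forcing will first show up as inverted-element errors.
* The diffusion weak form is integrated over the current configuration
  literally (no Piola/volume-change correction of `D`); the induced growth
  of conduction with stretch is part of the model as adopted.
* Voltage-row holding of scar nodes means a scar region's boundary nodes
  (shared with healthy elements) still participate in conduction; only
  fully-enclosed scar nodes are frozen.
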