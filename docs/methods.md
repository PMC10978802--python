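# Methods

This note documents the models, numerical methods and design choices in
`nemaindent`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the known limits are.

## The mechanical model

A segment of the adult *C. elegans* trunk is idealized as a straight
circular cylinder of three concentric, perfectly bonded tissue
compartments (inside-out): the **pseudocoelom** (body cavity with internal
organs, default diameter 26.3 µm), the body-wall **muscle** layer (width
1.0 µm), and the **cuticle merged with the hypodermis** (0.6 + 0.1 µm,
one 0.7 µm shell), giving interface radii 13.15 / 14.15 / 14.85 µm. The
cylinder length defaults to 90 µm (≈3 outer diameters) so that end
effects at the central contact are negligible; doubling the length changes
the indentation response by well under 1%.

Each compartment is an isotropic, nearly incompressible **neo-Hookean**
solid in the decoupled form

    W(F) = C10 (Ī₁ − 3) + (1/D1) (J − 1)²,

with `Ī₁ = J^{-2/3} tr(FᵀF)`, `C10 = µ/2`, `D1 = 2/κ`, and
`µ = E/(2(1+ν))`, `κ = E/(3(1−2ν))`. Tissue incompressibility is imposed
approximately through ν = 0.49 for all compartments (configurable up to
0.499; the response changes by ~1% between the two, see *Numerical
choices*). Young's moduli `E` are the free parameters, in kPa; the
package-internal unit system is µm–nN–kPa (1 nN/µm² = 1 kPa).

The pseudocoelom is modelled as a solid near-incompressible compartment
whose stiffness stands in for the hydrostatic pressure of the cavity; no
explicit internal-pressure load is applied. This follows from calibrating
a Young's modulus (not a pressure) per compartment; the near
incompressibility transfers the surface deformation to the deep
compartments, which is what makes the pseudocoelom modulus identifiable
from a sub-µm surface indentation at all.

## Indentation simulation

The AFM probe is a rigid sphere of radius 5 µm (the 10 µm glass bead)
descending onto the top generator of the cylinder at mid-length. Two
mirror symmetries (the vertical plane containing the axis and the
transverse plane through the contact point) reduce the domain to a
quarter; symmetry planes carry zero normal displacement. The worm rests
on a rigid frictionless plane (the agarose bed); a "pinned bottom line"
support is available as a sensitivity alternative and changes the
response by <0.5%. The remote end cross-section is free.

**Discretization.** Structured all-hexahedral butterfly (O-grid) meshes:
a half-square core inside the pseudocoelom, blended rings to the
pseudocoelom boundary, then conforming annular rings through muscle and
cuticle (no element straddles an interface), extruded along the axis.
One target edge `h = 0.7 µm / 2^level` controls the circumferential
spacing at the contact apex, the through-thickness subdivision and the
first axial layer; spacing grows geometrically away from the contact.
`level=1` (the production default, ~4200 elements, minimum contact edge
0.33 µm) matches the 0.4 µm optimum reported by the study's own mesh
convergence analysis; `level=0` is a screening mesh and `level=2` a
convergence-check mesh.

Elements are 8-node trilinear hexahedra with 2×2×2 Gauss quadrature and
**mean-dilatation (B-bar)** volumetric treatment: the deviatoric energy is
integrated pointwise while `(1/D1)(J−1)²` is evaluated at the
element-average dilatation, the standard remedy for volumetric locking of
displacement elements (verified: confined compression at ν = 0.49 vs
0.499 differs < 5%; a ν = 0.499 thick-walled-annulus problem matches the
Lamé solution within 2%).

**Contact.** The indenter acts through penalty contact integrated at 2×2
Gauss points of the candidate surface faces: the pressure
`p = κ_p⟨−g⟩` (gap `g`, penalty `κ_p = 100 E_max / h_face`) is
consistently distributed to face nodes, making the total force a smooth
function of the contact-patch boundary. Node-lumped penalty springs are
retained for the support plane, whose initial line contact at exactly
zero gap usefully regularizes the vertical rigid-body mode, and as a
public API. Doubling the penalty moves the set-force depth by < 1%;
converged states are penalty-insensitive and frictionless (forces are
purely normal; complementarity holds at the quadrature points).

**Solution.** Total Lagrangian quasi-statics, solved by Newton-Raphson
with displacement-controlled load stepping, automatic step cutback, a
backtracking line search (which also rejects trial states with inverted
elements), and linear extrapolation of the converged path as the next
step's initial guess (skipped during the first steps while the contact
patch forms). Linear systems use a sparse LU with a fixed
reverse-Cuthill-McKee ordering; the factorization is reused across
iterations, with contact-stiffness changes applied as low-rank Woodbury
corrections and refactorization triggered by residual stalls. The solver
is deterministic; repeated runs are bit-identical. Under the set-force
protocol the terminal point is refined by a secant iteration on the
descent until the converged reaction meets the set force within 1e-3 nN,
so every reported (δ, F) sample is a true equilibrium state.

**Protocols.** `set_force_nN` (the study's 450 nN AFM protocol;
terminates at the set force) or `max_depth_nm`; an explicit
`depth_schedule_nm` evaluates exact depths for calibration. Indentation
depth is defined as sphere descent after first touch, identical to the
processed tip-sample displacement of the AFM chain; cantilever compliance
is an acquisition effect and lives in the processing/synthesis modules.

## AFM curve processing

Raw records (force vs piezo position) pass through the standard chain:

1. **Baseline**: a line fitted to the iteratively grown flat pre-contact
   segment is subtracted (removes offset and linear drift).
2. **Contact point**: first sample exceeding 5× the pre-contact noise σ
   for 10 consecutive samples, then refined by extrapolating the
   spherical-contact power law `F^{2/3} ∝ (piezo − p₀)` back to zero
   force, which removes the systematic late-detection bias of threshold
   rules under noise. Both constants are configurable; the study
   delegated this step to vendor software.
3. **Cantilever bending**: tip-sample displacement is piezo travel minus
   the cantilever deflection `F/k` (nm, for F in nN and k in N/m).

Summary quantities follow the study's definitions: the **overall Young's
modulus** from a least-squares fit of the Hertz/Sneddon sphere model
`F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` (default R = 5 µm, ν = 0.5, entire
post-contact curve; the model is linear in E so the fit is a single
normal equation), the **bulk stiffness** as the OLS slope over
`[0.5 δ_max, δ_max]`, and treated/control stiffness ratios.

## Inverse calibration

The compartment moduli are estimated by minimizing the RMS force misfit
between the FE forward curve and a target curve, on the target's own
displacement grid, in log10-modulus space within bounds (default
10–10⁴ kPa per compartment, covering all reported values). The default
optimizer is a bounded trust-region Gauss-Newton (finite-difference
Jacobian, `diff_step` 0.02 dex): the misfit valley is narrow and curved,
and a derivative-free simplex (available as `method="nelder-mead"`)
traverses it an order of magnitude more slowly. Forward evaluations run
on the screening mesh with a warm-started engine (state caching per
depth across evaluations, materials swapped in place), ~4 s per misfit
evaluation; the final misfit can be re-evaluated on the production mesh.

A local sensitivity diagnostic (|∂ RMS/∂ log₁₀E| per compartment, ±0.05
dex central differences) is reported with every fit. The misfit carries a
pronounced trade-off direction between the muscle and pseudocoelom
moduli: at 2% force noise on a sparse (~20-point) curve the pair is only
constrained to a few tens of percent individually, while dense (AFM-
resolution) targets restore recovery to ~10%. This mirrors the wide
muscle ranges the study itself reports.

## Synthetic data

`nemaindent.synth` emulates the acquisition: a flat pre-contact baseline
(optional offset and linear drift), a contact point, a post-contact rise
from either the closed-form Hertz model or the FE forward model, mapped
to piezo position including the cantilever deflection `F/k`
(k = 7.5 N/m default, within the study's 5.79–10.81 N/m), sampled at
1 nm, with seeded Gaussian force noise. Fixtures return machine-readable
ground truth. What it deliberately does not emulate: instrument drift
nonlinearities, adhesion/snap-in, piezo hysteresis, biological
heterogeneity along the body, or curve-to-curve variation between
animals — so passing recovery tests validate the algorithms, not the
biology. Scenario presets carry the study's calibrated moduli
(BDM_mean 150/1200/840, BDM_salt_control 105/390/880, high_salt
90/650/76, aldicarb 140/950/94 kPa; 450 nN set force).

## Numerical choices and measured behaviour

* Newton tolerance 1e-8 (relative residual) for production runs, 1e-6
  for calibration search; load steps 0.06–0.08 µm descent (path
  independence verified: halving the step changes forces < 0.1%).
* Penalty factor 100 × stiffest modulus × local edge: chosen by the
  penalty-doubling criterion (doubling changes the set-force depth by
  < 1%).
* Degenerate inputs: zero-width compartments drop out of the geometry
  (homogeneous-cylinder limit); ν = 0.5 exactly and non-positive moduli
  are rejected with named-field errors; element inversion raises with
  element ids, and solver failures return the partial history flagged.
* **Structural softness relative to the half-space Hertz solution.** The
  homogeneous worm cylinder converges to ~12% below the analytic
  sphere-on-cylinder Hertz force (effective radius 4.32 µm): the free
  cylinder cross-section ovalizes under the concentrated top load. This
  is converged physics of the idealized free cylinder, not a numerical
  artifact (insensitive to refinement level, penalty, support model and
  ν; a clamped far end recovers only ~3%). The mechanics core is
  therefore verified against Hertz on a large homogeneous block
  (agreement within ~4% up to 250 nm), where the half-space assumption
  actually holds.
* **Through-thickness convergence.** With face-integrated contact the
  in-plane and axial directions are converged at the production mesh
  (level 0 vs 1: 0.6%), but refining the through-thickness layering
  alone still softens the 300 nm force by ~7–8% (level 1 vs 2): the
  familiar slow bending convergence of first-order hexahedra in thin
  stiff layers. The production level matches the study's own 0.4 µm
  optimum, and its forward depths reproduce the published values; the
  fully layer-converged model is systematically softer. Removing this
  would require enhanced-strain (incompatible-mode) elements — a known
  limitation, not currently implemented. Diagnostic overrides
  (`_h_inplane`, `_h_layers`, `_h_axial` in `generate_mesh`) expose the
  behaviour.
* **Shallow-depth compartment coupling.** In this model the stiff
  pseudocoelom engages essentially from first touch, so softening the
  muscle while stiffening the pseudocoelom produces a curve that is
  never measurably softer than the calibrated one at shallow depth — the
  discrimination of such "wrong-compartment" alternatives rests on the
  pronounced extra stiffness they show beyond ~250 nm.

## Problem sizes

Default test and acceptance runs use the level-0/level-1 meshes
(~1.9k / 4.2k elements, 7k / 15k DOF); calibration searches run ~40–60
forward evaluations on the level-0 mesh. These sizes were chosen as the
smallest at which the screening mesh tracks the production mesh to well
under the acceptance tolerances.
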