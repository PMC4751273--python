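# Methods

## Model

The simulator treats a 2D brain slice as two co-located continua. Every
tissue point carries an extracellular-space (ECS) concentration *c* and a
basement-membrane concentration *c_b* — the "two layers on one geometry"
idealisation: perivascular pathways thread the parenchyma densely enough
that both compartments exist everywhere, and the vascular tree is not
resolved. The governing equations are

- ECS: ∂c/∂t = ∇·(D\*∇c) − (**u**·∇)c − k_b c − k_d c
- membrane: ∂c_b/∂t = −(**u**_b·∇)c_b + k_b c

Take-up at rate k_b moves tracer from ECS to membrane; it is exchange, not
loss, so the two-compartment total is conserved in the absence of boundary
sinks. Degradation k_d defaults to zero (dextran is not enzymatically
degraded). The membrane compartment is advection-only: convection dominates
there by assumption, and an explicit finite-difference scheme needs no
regularising diffusion, so its diffusivity is exactly zero.

Boundary conditions: zero normal flux on all brain boundaries for both
fields; the needle walls are interior no-flux obstacles. The needle tip
holds c = c₀ for the injection window (0–120 s). After the injection the tip
follows the injection schedule literally and becomes a c = 0 Dirichlet sink
(`dirichlet_zero`, default); a `no_flux` mode is provided because the
observable far-field distances are insensitive to the choice (0.725 vs
0.731 mm for the baseline case at the 7-min mark) and the 50 µm sink is a
modelling idealisation either way. The membrane field is never prescribed
at the tip.

## Parameters

All internal units are SI; mol m⁻³ equals mM numerically.

| parameter | default | meaning |
|---|---|---|
| D\* | 8.7e-11 m² s⁻¹ | effective diffusion coefficient of 3 kDa dextran in gray matter (tissue-measured, temperature-corrected) |
| λ_gray | 1.60 | gray-matter tortuosity (isotropic) |
| λ_white,par / perp | 1.47 / 1.68 | white-matter tortuosity along/across fibres |
| u | 1.75e-7 m s⁻¹ | bulk-flow speed along white-matter fibres |
| u_b | 8.33e-6 m s⁻¹ | apparent perivascular drainage speed (2.5 mm in 5 min) |
| k_b | 2.5e-4 s⁻¹ | take-up rate into basement membranes |
| c₀ | 0.33 mol m⁻³ | injected concentration (1 µg/µl of 3 kDa dextran) |
| t_inject / t_total | 120 s / 1920 s | injection window / simulated span |
| detection fraction | 1e-3 | detection threshold relative to c₀ |
| C_max | 0.5 | Courant-number bound |

D\* is taken as the *effective* gray-matter coefficient. The free-medium
value needed for the white-matter tensor is recovered as
D_free = D\*·λ_gray², then divided by the white λ² per axis and rotated to
the fibre frame. This keeps gray-matter diffusion exactly at the measured
value. The temperature-correction utility
(D·(T_target/T_ref)·(µ_ref/µ_target)) is provided standalone; the default
D\* is already the corrected value, and since the underlying measurement
temperature is ambiguous the utility takes explicit temperatures rather
than guessing.

The ten-case matrix (A1–C4) multiplies (D\*, u, u_b, k_b) per case; the
canonical rows are validated at construction, and `custom_case` exposes
arbitrary multipliers for mechanism isolation.

## Synthetic geometry

The atlas-derived slice shapes are not available as vector data, and the
B-case results show white-matter placement is immaterial, so the geometries
are parametric stand-ins with the three quantitative anchors fixed:

1. coronal bounding box 8.0 × 5.5 mm (sagittal 13.7 × 5.5 mm),
2. needle tip at (5.7, 2.8) mm (sagittal (6.1, 3.9) mm),
3. brain boundary 2.46 mm from the tip in the drainage (+x) direction.

Anchors 1–3 are mutually consistent only if the brain box is offset: the
interior spans x ∈ [0.16, 8.16] mm, placing the tip ~1.5 mm right of the
brain midline (which matches how the injection site is described
anatomically). The downstream boundary is drawn as a circular arc of radius
2 mm centred 0.46 mm downstream of the tip, so the farthest boundary point
from the tip is exactly the 2.46 mm clearance and every other reachable
boundary point is closer. This is what pins the full-model detection
distance at 2.46 mm at both the 5- and 30-min marks: the drainage band
accumulating along a *straight* vertical boundary would keep growing its
Euclidean extent as it widens, which contradicts the observed pinning; a
convex boundary, like the real slice outline, does not.

White matter is a corpus-callosum-like elliptic band above the injection
site with fibres along x, placed so the 0.1 % contour of the baseline
diffusion case never reaches it within 32 min. That choice makes the
bulk-flow insensitivity exact in this geometry rather than approximate; it
does not affect any targeted number. The sagittal-like slice is provided
for completeness (drainage +y) without the arc-cap calibration, since its
drainage-case distances are dominated by a transient the model does not
reproduce and are excluded as targets.

Rasterization is uniform Cartesian with stair-step boundaries; labels are
assigned by cell-centre membership. The needle is 50 µm wide (±1 cell),
runs from the top boundary to the tip, and its lowest row forms the inflow
cells. Homogeneous all-gray calibration rectangles (optionally with a
central point source) support the analytic oracles.

## Discretization and numerics

- **Diffusion**: conservative face fluxes, second-order central; face
  coefficients are arithmetic means of the cell tensors; tensor cross terms
  (rotated fibre axes) use face-averaged one-sided gradients. Inflow cells
  borrow the gray coefficient so the tip face has a sensible conductance.
- **Advection** (both fields): first-order upwind *fluxes* with zero flux
  through boundary faces. For the piecewise-constant velocities of this
  model the flux divergence equals the advective form (u·∇)c in the
  interior, and the flux form makes boundary accumulation and exact mass
  conservation automatic. Upwinding adds numerical diffusion of order
  u·dx/2 ≈ 1e-10 m² s⁻¹ to the membrane field at the production
  resolution; it broadens the drainage front but cannot move its leading
  edge faster than u_b, and the front carries ~30× the detection threshold,
  so detection distances are insensitive to it.
- **Time stepping**: forward Euler with one global step per run,
  dt = min(C_max·dx/max(|u_x|+|u_y|), 0.9·dx²/(4·max eig D)), rounded down
  so an integer number of steps lands exactly on each record time (10 s
  cadence by default). At dx = 25 µm this gives dt ≈ 1.25–1.43 s
  (0.135 s for the 10× diffusion case).
- **Safety**: any non-finite value or |c| > 10·c₀ raises a divergence error
  naming the simulation time. Non-negativity holds structurally for the
  default (axis-aligned) tensors under the stability bound.
- **Determinism**: a run is a pure function of its inputs; repeated runs
  produce byte-identical CSV outputs.

## Detection metric

The detection distance is the maximum Euclidean distance from the needle
tip to the centre of any cell at ≥ 0.1 % of c₀, scanned by default over the
pointwise maximum of both compartments ("combined") — a fluorescence
readout does not distinguish compartments, and the drainage front detaches
from the diffusion cloud, so disconnected super-threshold regions count
deliberately. Per-compartment series are always recorded alongside.
Distances are cell-centred (no sub-cell contour interpolation; quantisation
error ≤ dx/√2). Summary tables report distances at 5 and 30 min *after the
end of the injection*, i.e. simulation times of 7 and 32 min, plus the
first-passage time to 2.5 mm (linear interpolation between records, an
explicit "not reached" otherwise).

## Validation

The test suite checks the solver against independent oracles rather than
against itself: the 2D heat kernel for a point release (< 2 % L2 at
dx = 25 µm; measured 0.08 %), the closed-form two-box exchange solution for
pure take-up (dt-order agreement), exact centroid transport for membrane
pulses, per-step mass-ledger conservation (≤ 1e-10 relative; measured at
machine precision), a duplicate loop-coded implementation of the gradient
indicator, and a uniform-grid refinement study replacing adaptive meshing:
the 7-min baseline detection distance moves 0.5 % when dx is halved from
25 to 12.5 µm, and fixed probe points 0–0.6 mm from the tip are compared
across spacings via `periclear converge`.

Problem sizes: production runs use the coronal-like slice at dx = 25 µm
(320 × 220 cells, ~62k tissue cells), chosen because the refinement study
shows the distance metric converged there and a full 32-min case runs in
seconds on one CPU; analytic validations use 240 × 240 calibration grids.

## Limitations

- 2D slices with a single homogenized gray and white material; no vascular
  tree, no atlas shapes, no 3D.
- Drainage is a single constant velocity per slice, not flow along real
  vessel paths; the 2.46 mm pinning is a geometric consequence of the
  emulated boundary.
- First-order upwinding smears sharp advected fronts; acceptable for
  distance metrics, not for reproducing contour shapes quantitatively.
- The synthetic geometry reproduces the anchored macroscopic numbers; it
  does not establish anything about white-matter routing in real anatomy,
  and passing tests on it validate the transport model, not the anatomy.
- The injection's own convective flow is neglected (supported only as a
  parameter override), matching the finding that it is negligible at
  realistic speeds.
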