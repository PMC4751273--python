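# periclear

A 2D simulator of solute clearance from brain gray matter, built to answer a
sharp quantitative question: can diffusion through the extracellular space
(ECS) alone explain how quickly an injected tracer reaches the brain surface,
or is convective perivascular drainage along vascular basement membranes
required?

Soluble metabolites such as amyloid-β leave the brain parenchyma by first
diffusing through the narrow ECS and then entering 100–150 nm basement
membranes in the walls of capillaries and arteries, along which they drain
convectively. Failure of this lymphatic-like pathway with age is implicated in
cerebral amyloid angiopathy and Alzheimer's disease. `periclear` models the
two routes as two coupled concentration fields on a synthetic brain-slice
geometry and measures how far a dextran-like tracer spreads from an injection
site.

## Model

Two fields live on every tissue point of a 2D slice:

- ECS concentration *c* (mol m⁻³):

  ∂c/∂t = ∇·(D\* ∇c) − (**u**·∇)c − k_b·c

  with effective (tortuosity-scaled) diffusion tensor D\* (isotropic
  D\* = D/λ² in gray matter; anisotropic along white-matter fibre axes),
  slow bulk flow **u** along white-matter fibres, and first-order take-up at
  rate k_b into the membrane compartment.

- basement-membrane concentration *c_b*:

  ∂c_b/∂t = −(**u**_b·∇)c_b + k_b·c

  pure advection at the apparent drainage velocity **u**_b (no diffusion),
  sourced by the take-up term. Take-up is exchange, not loss: total tracer is
  conserved.

A 50 µm injection needle prescribes c = c₀ at its tip for the first 2 min
(Dirichlet), then becomes a c = 0 sink (or no-flux, by configuration). All
outer boundaries are no-flux, so tracer carried by the drainage field
accumulates where the drainage direction meets the brain boundary.

The headline observable is the **maximum detection distance**: the largest
Euclidean distance from the injection site to any cell whose concentration
(in either compartment) is at least 0.1 % of c₀. Regimes are characterised by
the Péclet number Pe = L·U/D with L = 5.5 mm the brain height: Pe ≈ 11 for
white-matter bulk flow, Pe ≈ 527 for perivascular drainage.

Discretization is a uniform Cartesian grid with conservative central
differences for diffusion, first-order upwind fluxes for advection, and
forward-Euler time stepping under a combined CFL/diffusive stability bound.

## Worked example

Ten canonical cases probe the mechanisms: A1–A3 diffusion only (1×, 5×, 10×
D\*), B1–B3 add white-matter bulk flow (1×, 5×, 10× u), C1–C4 add drainage
and take-up at varying strengths. Reproduce the case table on the synthetic
coronal-like slice (8 × 5.5 mm, needle tip at (5.7, 2.8) mm, dx = 25 µm):

```sh
periclear suite --out results/coronal
```

which prints (distances measured 5 and 30 min after the end of the 2-min
injection):

```text
case    5 min (mm)  30 min (mm)   t to 2.5 mm (s)  compartment
--------------------------------------------------------------
A1            0.73         1.16       not reached  combined
A2            1.55         2.91              1219  combined
A3            2.37         4.02               419  combined
B1            0.73         1.16       not reached  combined
B2            0.73         1.16       not reached  combined
B3            0.73         1.16       not reached  combined
C1            2.46         2.46       not reached  combined
C2            1.85         2.46       not reached  combined
C3            0.72         2.46       not reached  combined
C4            1.55         2.88              1269  combined
```

Reading the table: baseline diffusion (A1) spreads only ~0.73 mm in the
5 minutes after injection — far short of the ~2.5 mm the tracer is observed
to travel in vivo — and bulk flow (B-cases) changes nothing. With the full
model (C1) the drainage front reaches the brain boundary, 2.46 mm from the
tip, within those 5 minutes and stays pinned there ("t to 2.5 mm" stays
empty only because the boundary itself lies at 2.46 mm < 2.5 mm). Only a
tenfold-inflated diffusion coefficient (A3) comes close without convection.
Diffusion alone cannot account for the observed clearance speed.

The same workflows are available as library calls:

```python
import periclear as pc

params = pc.Parameters()                       # defaults: 3 kDa dextran
grid = pc.make_slice(pc.coronal_like_spec(dx=25e-6))
result = pc.run_simulation(pc.build_case("C1"), grid, params)
times, dist = result.distance_series("combined")
```

Other entry points: `periclear simulate` (one case), `periclear converge`
(probe-point grid-refinement study), `periclear geometry` (region census and
VTK export).

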