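# Methods

This note records the model, numerical scheme, parameter conventions and
design decisions behind `limbrd`, and what the synthetic generators do and do
not emulate.

## Governing equations and compartments

The simulator integrates systems of coupled stochastic reaction–diffusion
PDEs, ∂u/∂t = f(u, x, t) + D∇²u + η(u, t), for a user-declared vector of
reactants over three compartments: the 2D mesenchyme (triangular elements),
the 1D ectoderm boundary (linear elements, each coinciding with exactly one
mesenchyme triangle edge along the limb arc) and a non-spatial global
compartment. Reaction terms, diffusivities, noise amplitudes and initial
conditions are free expressions over the model's entities; expressions may
reference global entities and entities of their own compartment, plus the
reserved symbols `t` (hours) and `x`, `y` (domain length unit, `y` distal).
Variables are named expressions re-evaluated each step — never integrated,
never diffusing; pre-defined patterns are feedforward inputs fixed with
respect to the model. Variable-to-variable references must be acyclic;
cycles are rejected at validation rather than solved as algebraic
constraints, because variables are defined as explicit expressions.

Initial-condition expressions may reference only parameters, patterns and
(t, x, y): reactants do not exist before initialisation and variables may
depend on reactants, so admitting them would make t₀ ill-defined. This is a
deliberate narrowing of the general same-compartment visibility rule.

## Spatial discretisation

Diffusion uses a two-point finite-volume flux. For adjacent triangles i, j
sharing an edge of length L_ij with centroid distance d_ij,

    F_ij = D_ij · L_ij · (u_j − u_i) / d_ij,   rate_i = (1/A_i) Σ_j F_ij,

with D_ij the harmonic mean of the element diffusivities (so an element with
D = 0 blocks flux) and zero flux through exterior edges. Fluxes cancel
pairwise, so Σ u·A is conserved to machine precision per step. The ectoderm
chain uses the same scheme in 1D with element lengths as volumes. On a unit
square at mesh edge 1/20 the operator's slowest non-trivial decay mode is
within ~2% of the analytic heat-equation rate D·π² (the acceptance script
recomputes this).

Meshes are generated by subdividing the boundary polygon's segments (never
moving vertices), seeding the interior with a hexagonal lattice at 0.9× the
target edge length kept ≥ 0.5 spacings away from the boundary, Delaunay
triangulation, and filtering to the polygon. The result is verified to tile
the polygon exactly — every boundary segment is an edge of exactly one
triangle and the summed area matches — otherwise the generator retries with
a wider margin and finally raises. This replaces a constrained quality
mesher; on the shapes the package generates it achieves max edge ≤ 1.5×
target and minimum angles above ~20°, and it is fully deterministic.

## Growth, deformation and remeshing

Within each hourly stage frame, growth is treated as smooth: vertex
positions blend linearly from the frame's start configuration to its end
configuration (the published platform does not state its within-interval
interpolation; linear-in-time is this package's convention). After every
step the state is diluted by the per-element area ratio so the per-element
amount u·A is invariant — deformation advects material passively. At frame
changeover, fields transfer to the next frame's mesh proportionally to
element intersection areas (exact polygon clipping, candidate pairs from an
STR bounding-box tree; intersections below 10⁻¹² of an element's area are
discarded). Each new element takes the overlap-weighted average
Σ u_old·A_int / Σ A_int: normalising by covered area rather than the
element's own area preserves constants exactly and is identical to within
float precision when the meshes tile the same region; essentially uncovered
elements (< 10⁻⁶ of their area) copy the nearest covered element's value.
The ectoderm remaps by interval overlap in a shared arc-length
parameterisation. Concentration is the primitive; the remap conserves the
integral, not pointwise values.

The synthetic limb trajectory is constructed so that consecutive remap
regions are *identical* polygons: the next frame's boundary vertices are
defined as the images of the current frame's boundary vertices under the
growth map (triangulation afterwards only subdivides segments). Without
this, two independently sampled polygonal outlines of the same smooth curve
would disagree by O(h²·curvature) in area and cross-remesh conservation
could never reach the 10⁻⁸ level the tests demand; with it, conservation
holds to ~10⁻¹⁴.

Boundary correspondence between stages is arc-length-proportional within
each boundary portion, anchored at the flank-edge endpoints and at the two
flank-rectangle corners (piecewise per straight segment — without the corner
anchors, vertices drift across corners as the flank grows and boundary
triangles collapse). Interior vertices follow the harmonic (graph-Laplace)
extension of the boundary displacement with Dirichlet data, in place of
inverse-distance weighting: IDW flattened thin boundary triangles on late
frames (inverted elements), while the harmonic extension is the standard
mesh-morphing choice and keeps every frame's deformed configuration valid.

## Time stepping, noise and stability

One explicit update per step; reaction, diffusion, coupling, intervention
sources and noise are all evaluated from the same pre-step state (no
sequential splitting):

    u ← u + dt·(f + diffusion + coupling + sources) + η·√dt·ξ,  ξ ~ N(0,1).

Noise follows the Euler–Maruyama discretisation of a Wiener process with one
independent draw per element, per species, per step; amplitudes are
per-element and not area-normalised by default, with an optional
`noise_sqrt_area_scaling` config flag that divides each draw by the square
root of the element measure for SPDE-consistent behaviour under mesh
refinement. The RNG is a single PCG64 stream per
simulation seeded by the config; draws are species-major in reactant
declaration order, and species whose noise expression is the literal `0`
draw nothing — so noiseless simulations are bitwise independent of the seed,
and equal seeds give bitwise-identical results. Clamped species are floored
at zero after the update. Ensemble variance across independent elements
reproduces σ²·t within a few percent (acceptance script).

The explicit-diffusion stability bound dt ≤ 0.5·min_i A_i / Σ_j D_ij L_ij /
d_ij is evaluated at t₀ and after each remesh; violation warns by default
and errors when `stability_check` is set. The factor 0.5 is a safety margin:
the literal CFL limit is A_i/Σw.

Compartment coupling must conserve the combined amount Σu·A + Σu·L. A
symmetric exchange `k·(u_other − u_self)` added to both sides does not (the
two elements have different measures), so the ectoderm element receives
k·(u_m − u_e) and its owner triangle the opposite flux weighted by L_e/A_m.
This conserves exactly and equilibrates the two concentrations
monotonically.

Virtual experiments: a bead occupies exactly one element (resolved from its
(x, y) position at activation, then tracked as a material point: its element
centroid is carried through the deformation and re-located after each
remesh) and adds a constant source rate to its target reactant while the
window is open. Timed interventions such as AER removal or global
overexpression are expressed through the model language itself (e.g.
multiplying a production term by `step(t_off − t)`) or as
`expression_override` interventions; they are not special-cased in the
integrator.

## Digitisation, comparison, fitting

Digitisation maps pixel centres (col + ½, row + ½) through a user-supplied
affine alignment into domain coordinates and averages, per triangle, the
intensities of the pixels whose centres fall inside it (point-in-triangle
assignment rather than exact pixel clipping; the error is sub-pixel and the
supersampling oracle test bounds it at ~10⁻³ for 256² images). Intensities
are normalised by bit depth, optionally inverted first (dark stain = high
expression); elements containing no pixel centre take the mean of the
nearest-pixel intensities at their vertices. Staging — assigning a
developmental stage to an image — is an external published system's asset
and out of scope; the caller supplies the stage frame and alignment.

Pattern comparison is element-wise subtraction with an area-weighted RMS
summary. The fitting objective is the weighted, area-weighted mean squared
difference between simulated reactants and target fields at target times —
least-squares with user weights is a convention here (the weighting across
time points is not otherwise prescribed); correlation-based metrics are a
documented extension point. The optimiser is bounded Nelder–Mead with
seeded random restarts, never evaluating outside the declared bounds;
derivative-free because remeshing makes the objective non-smooth in the
parameters.

## Synthetic generators and their limits

`make_limb_trajectory` emulates the canonical hourly limb-bud trajectory's
*bookkeeping* only: stage labels `mE{d}:{hh}` (hour index d·24 + hh;
inclusive frame count end − start + 1, so mE10:09 → mE12:08 gives 48
frames), a flank rectangle joined to a smoothly elongating half-ellipse arc
with a progressive distal bulge, strictly monotone area growth and exact
boundary hand-over. Defaults: base width 1.0 domain unit, initial length
0.8, elongation 0.04/h (roughly tripling limb length over the two-day
range), distal bulge 0.25, flank height 20% of current limb length, target
edge 0.12. These are round numbers chosen to give a plausibly
limb-proportioned, well-resolved domain; the outline is *not* the real
mouse hindlimb shape, and results on it demonstrate the machinery, not
mouse biology. The flank's proximal edge abuts the embryo body: it carries
no ectoderm elements and is a zero-flux wall; its dimensions are
configurable because no canonical value is available.

The builtin model catalogue (`brusselator`, `turing_two_species`,
`pd_feedforward_toy`, `pord_toy`) ships structurally analogous toy
parameterisations of classic patterning systems, labelled as such — the
published case-study equations and parameter sets are not reproduced here.
The Brusselator uses the standard form u̇ = a − (b+1)u + u²v, v̇ = bu − u²v
with a = 2, b = 3.5, Dv/Du = 10: above the Turing threshold
b_c = (1 + a√(Du/Dv))² ≈ 2.67, below the Hopf threshold 1 + a² = 5, with
critical wavelength ≈ 0.35 so a unit square holds ~3 periods.

## Test and acceptance problem sizes

The suite and the acceptance script use deliberately small problems — unit
squares at mesh edges 0.045–0.2 (≈ 100–2700 elements), limb-trajectory
slices of 8–12 frames at edge 0.14–0.15, 20-hour Turing runs at dt = 0.002
(within the CFL bound of the finest mesh), and a 60-evaluation fit budget —
sizes at which every acceptance property is already sharply resolved. The
"1000 replicates" of the noise law are realised as ≥ 1000 independent
elements across two seeds: with f = D = 0 each element is an i.i.d. copy of
the same scalar SDE, so element variance and ensemble variance coincide.

## Known limitations

* Explicit integration only; stiff models need small dt (no implicit
  solver, no GPU path).
* 3D domains, adaptive refinement and GRN-controlled (mechanics-driven)
  growth are out of scope; the domain trajectory is prescribed and does not
  respond to the simulated network.
* The mesher is a filtered-Delaunay generator verified per call, not a
  guaranteed-quality constrained refinement algorithm; pathological
  boundaries can make it raise rather than degrade.
* With the default per-element noise interpretation, refining the mesh
  changes the effective spatial noise correlation; models comparing noise
  across resolutions should enable `noise_sqrt_area_scaling`.
* Digitisation assumes the image is already aligned; no registration or
  outline extraction is provided.
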