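# Methods

`kneefe` builds subject-specific finite element (FE) models of the medial
tibiofemoral compartment from five anatomical dimensions measurable on a
calibrated knee radiograph (or MRI), simulates the stance phase of walking
with a fibril-reinforced poroviscoelastic (FRPVE) cartilage model, and
compares the resulting biomechanical trajectories between imaging
modalities with 1-D statistical parametric mapping (SPM). This note
records the models, the defaults, and the design choices that were
genuinely open.

## Anatomical dimensions and calibration

Five distances drive the whole pipeline: maximum anterior–posterior (AP)
length of the medial and lateral femoral condyles, medial and lateral
tibiofemoral joint space width (JSW), and maximum medial–lateral (ML)
width of the distal femur (the transepicondylar distance). Radiographs are
calibrated with a metal disc of known physical diameter (30 mm) placed in
the field of view; the pixel pitch is `known_diameter / detected_diameter`.
Disc detection is Otsu thresholding → connected components → a circularity
filter (4πA/P² ≥ 0.85) → equivalent-area diameter. On noise-free synthetic
rasters this recovers the diameter to well under one pixel; the acceptance
script verifies a 30 mm disc rendered at the protocol pitch of
0.148 mm/px is recovered within 1%.

Manual landmarking on real images is out of scope: dimensions enter as
numeric CSV records (subject × modality × repeat), validated against the
ordering invariants (JSW < AP on each side, ML > both JSWs).

## Synthetic atlas library

Real atlas libraries are segmented from MRI; here the geometry is
parametric so the pipeline runs from dimensions alone. Axes are x = AP,
y = ML, z = inferior→superior (mm). Per atlas:

- **Tibial cartilage**: a structured hex block spanning AP extent × half
  the ML width (compartment models cover half the joint), flat at the bone
  interface, with a shallow dished articular surface (0.3 mm rise from
  centre to rim).
- **Femoral cartilage**: a constant-thickness cap whose articular surface
  is an elliptic paraboloid (sagittal radius 35 mm, frontal 25 mm —
  typical condylar curvatures), spanning the same footprint. The minimum
  articular-surface gap at the compartment centre equals
  `JSW − t_femoral − t_tibial`, so the radiographic joint space is
  reproduced by construction. Cartilage thicknesses default to 45% of the
  medial JSW each (the radiographic joint space is mostly cartilage),
  leaving a 10% free gap at the reference pose.
- Default resolution 4×4×3 tibial elements (femoral 4×4×2); in-plane
  element counts must be even so a node sits at the compartment centre
  where the JSW is measured. Normalized depth `h_z` is assigned at element
  layer midpoints, 0 at the articular surface, 1 at the bone interface.
- **Gait waveforms** travel with each atlas: a piecewise-linear double-hump
  axial reaction (peaks ≈ 2.5 body weights near 25% and 75% of stance),
  smooth flexion–extension (loading-response hump, pre-swing rise) and
  varus–valgus (±2°) curves, and a meniscus load-share profile
  (≈ 0.25–0.35). A per-atlas seed perturbs peak amplitudes (±10%) and
  phases (±3% stance) deterministically.

The default library holds 21 atlases with dimensions drawn uniformly from
ranges spanning non-narrowed adult knees (medial AP 52–64 mm, medial JSW
4.0–5.6 mm, ML 76–90 mm, …). The generator round-trips: measuring
AP/ML/JSW back from generated meshes recovers the inputs within 2%.

Meshes serialize as a flat Abaqus input-deck subset (`*NODE`, `*ELEMENT
TYPE=C3D8P`, `*NSET`, `*ELSET`, `*SURFACE`) plus JSON metadata; round
trips are lossless to 1e-9 mm.

## Template selection and morphing

All dimensions are normalized by the ML width, removing joint size; the
subject is scored against every atlas by the RMSE over the four remaining
ratios and the argmin wins (a sum-of-absolute-differences score is
available as `score="sum_abs"`; both orderings agree for balanced
differences, and RMSE over the 4-vector is the reading adopted). Ties
within 1e-12 break by lexicographic atlas id so library order never
matters.

The winning atlas is scaled anisotropically: x by the medial AP ratio,
y by the ML ratio, z by the medial JSW ratio, about the centroid of the
tibial contact face (keeping the contact region centred; the fixed point
of the scaling is otherwise arbitrary). Factors outside (0.5, 2.0) are
refused as "atlas too dissimilar". Scaling z by the JSW ratio means
cartilage thickness scales with the joint space — thickness is not
re-measured independently. Element volumes scale exactly by fx·fy·fz;
sets and `h_z` are untouched.

## FRPVE material model

Total Cauchy stress at a cartilage material point:

    sigma_t = sigma_nf + Σ_i sigma_f^i − p I

- **Nonfibrillar matrix** (`sigma_nf`): compressible Neo-Hookean with
  shear/bulk moduli from (E_m, nu_m); zero at F = I, objective, and
  matching linear elasticity with modulus E_m at small strain. The
  specific hyperelastic form is this package's choice; it is validated
  through limit behaviour, not against any particular published form.
- **Fibrils**: 4 organized primary directions follow a Benninghoff-style
  arcade — parallel to the articular surface (azimuths 0/90/45/135°) for
  h_z < 1/3, rotating linearly to surface-normal by h_z = 2/3 — plus 13
  secondary directions from a spherical Fibonacci lattice under a seeded
  random rotation (shared per tissue, reproducible). Each fibril is
  tension-only with elastic branch `sigma_e = E_0 ε + E_eps ε²` in
  parallel with a Maxwell overstress branch (secant spring modulus
  `E_0 + E_eps ε`, dashpot η, backward-Euler update). Under loading the
  transient stress exceeds the elastic branch and relaxes exponentially
  back to it at constant strain; η → 0 recovers the elastic branch
  exactly; compressed fibrils carry nothing and relax their history.
  Fibril strain is the stretch of the reference direction minus one; each
  fibril's 1-D stress acts as a rank-1 tensor along its deformed
  direction. Primary fibrils carry 3.009× the density of secondary ones
  (a literature-lineage constant, not identifiable here); weights are
  normalized to sum to one so a fully aligned network reproduces the
  branch stress.
- **Fluid**: fraction `n_f(h_z) = 0.8 − 0.15 h_z` for cartilage, 0.72 for
  meniscus. Permeability is constant at `k_0` (femoral 6, tibial
  18 × 1e-15 m⁴/(N·s), converted once to mm⁴/(N·s)); an optional
  void-ratio dependence exists behind a flag and is off by default.

Material parameters ship as YAML (`cartilage_femoral`, `cartilage_tibial`,
`meniscus`). The meniscus (transversely isotropic, stiff circumferential
axis E₃ = 159.6 MPa) is not meshed — its load share is subtracted from
the applied force — but its 6×6 stiffness assembly is provided and
verified against the isotropic degenerate case.

## Poroelastic u-p solver

Equal-order trilinear hexahedra (8-node, displacement + pore pressure, the
porous linear hexahedron element class), total-Lagrangian geometric
nonlinearity, backward Euler in time. Continuity uses `d(J)/dt` as the
volume-change measure with Darcy flux `−k ∇p`; all exterior surfaces are
sealed (no flux terms), matching the assumption of negligible fluid flow
during gait. Equal-order pairs are stabilized by local polynomial pressure
projection with coefficient `0.0005/μ`. This coefficient was chosen as the
smallest that suppresses checkerboard modes on the meshes used here:
larger values leak fluid volume visibly (the stabilization acts as
artificial intra-element compressibility), and the leak is what limits the
consolidation benchmark accuracy (~1%, halving under mesh/time
refinement). Consequences: the undrained limit is only clean for time
steps above ~1% of the consolidation time; see `consolidation_benchmark`.

Boundary conditions mirror the compartment model: tibial cartilage–bone
interface fully fixed; femoral cartilage–bone interface rigidly tied to a
reference point midway between the epicondylar attachments, where
flexion–extension (about ML) and varus–valgus (about AP) rotations are
prescribed and the axial force is applied along z (in-plane translations
fixed). A weak spring (0.05 N/mm) on the axial mode keeps the pre-contact
configuration solvable; its force contribution (< 0.2 N) is far below the
0.5% balance budget.

**Contact** is frictionless penalty between the femoral articular surface
and the triangulated tibial articular surface, enforced at the 2×2 Gauss
points of the femoral contact faces. Integration-point contact was chosen
over classic node-to-surface because the generator produces conforming
grids: every femoral node sits exactly above a tibial vertex, where facet
normals flip and Newton wedges into limit cycles; Gauss points never
align with master vertices. The master normal field is vertex-averaged
and barycentrically interpolated (continuous across facets); points
sliding past the plateau boundary keep a continuous force through a 2 mm
fade band (edge contact at high flexion). Penalty stiffness defaults to
50 N/mm³ — penetrations stay below ~2% of cartilage thickness and
doubling the penalty changes the peak contact pressure by well under 5%
(asserted in the tests). No fluid crosses the interface.

The Newton tangent is exact where it is cheap (analytic u-p coupling and
pressure blocks) and finite-difference where it is not: the element solid
block by forward differences of the element internal force (capturing
geometric, fibril and history terms), and each active contact point by
local differences of its force vector over the 21 involved dofs.
Convergence requires the residual to fall to 1e-5 of its initial value,
or — after at least one corrector pass — below 0.1% of the applied force
with the support-reaction sum matching the applied load within 0.25%
(half the 0.5% balance budget; an infinity-norm criterion alone does not
control the summed defect). A backtracking line search handles the
residual nonsmoothness inherent to penalty contact; when the iteration
nevertheless limit-cycles, the state is accepted only if its defect is
below 0.5% of the load *and* the reactions balance, otherwise the step
fails fast and adaptive load bisection takes over. Penalty contact thus
bounds, rather than eliminates, a small nonsmoothness floor (~0.1–0.2%
of the load) in the converged residuals.

Stance is mapped to 0.6 s (typical duration, configurable) on the
waveform grid (51 points by default, i.e. 50 implicit steps). The first
stance point is reached through a seating ramp: axial force in three
sub-increments, then the initial rotations — establishing contact before
rotating is far better conditioned than ramping both at once. Grids much
coarser than ~2° of rotation per step (e.g. 11 stance points) can defeat
the bisection fallback near toe-off and are not recommended.

Verification: 1-D consolidation of a laterally confined column against
the classical single-drainage series solution (< 2% of the applied load
at 0.1/0.5/1.0 characteristic times on a 20-element column, converging
under refinement); global force balance within 0.5% at every stance step;
the stress decomposition identity re-assembled independently from the
committed per-fibril history to 1e-10 at every Gauss point; zero-load
controls produce identically zero fields; a pure-axial load on the
symmetric geometry yields ML- and AP-mirror-symmetric contact pressure
within 5% (residual asymmetry from the diagonal facet split).

## Loading

Applied axial force at stance fraction q:

    F(q) = axial_BW(q) · BW · medial_fraction · (1 − meniscus_share(q))

with `medial_fraction = 0.5` (half the joint load through the medial
compartment) and the meniscus share taken from the matched atlas's
waveform profile unless overridden (a constant 0 is used in verification
runs). Rotational channels pass through unchanged.

## Trajectories and statistics

Outputs are element-centroid fields on the tibial cartilage: maximum
principal stress (of the total stress), maximum/minimum principal
logarithmic strain, fibril strain (largest tensile fibril-direction
strain over the 17 directions), fluid pressure, and the per-face contact
pressure (penalty force / face area, attributed through master vertices
so the facet split does not bias the field). Two statistics per parameter
and stance point, restricted to the contact region (faces with pressure
above 0.01 MPa, configurable):

- *mean*: unweighted average over contact-region element centroids;
- *peak*: the extreme element averaged with every element sharing at
  least one node with it (vertex adjacency, the most inclusive reading;
  face adjacency available), unweighted. For the signed minimum principal
  strain the extreme is the most compressive element.

Stance points with an empty contact region are NaN and excluded pairwise
downstream.

The statistical layer provides Shapiro–Wilk screening (delegated to
scipy), classical paired t-tests with two-sided CIs, ICC(3,1) (two-way
mixed, consistency, single measure) for triplicate intra-rater
reliability, and nonparametric 1-D SPM: the pointwise paired t trajectory
is compared against the (1−α) quantile of the max-|t| distribution over
sign-flip permutations (exhaustive when 2ⁿ fits the budget), and maximal
supra-threshold intervals are reported as clusters. Permutation SPM was
made the default because it is exactly implementable and self-validating;
a parametric random-field threshold is not provided. Normality screening
applies to 0-D summaries, not per grid point. No multiplicity correction
is applied across the 5 parameters × 2 statistics families (matching the
analysis protocol this mirrors); Bonferroni can be applied externally.
Family-wise error control of the permutation SPM is verified by
simulation (≈ 0.05 ± 0.02 over 400 null replicates of 20 subjects × 101
smooth-noise grid points).

## Synthetic paired study

Each virtual subject has true dimensions drawn from the library ranges
and a body weight in 600–1000 N. The MRI record observes the truth with
zero-mean noise (SD 0.4 mm for AP/ML, 0.15 mm for JSW, per repeat,
3 repeats); the radiograph record adds a per-dimension bias before the
noise — defaults +7.8 mm medial AP, +2.7 mm lateral AP, −2.0 mm ML,
0 for the JSWs — emulating projection and magnification effects that make
condyles read longer and the ML width slightly shorter on radiographs.
The bias magnitudes are configuration, not truth; with them at zero the
two modality records are identical and the pipeline must (and does)
select identical templates and report no SPM clusters.

What the synthetic study does *not* emulate: real segmentation/landmark
error structure, between-rater effects, KL-grade-dependent narrowing,
lateral-compartment or patellofemoral anatomy, and subject-specific gait.
Passing tests therefore demonstrate the *pipeline's* correctness and
sensitivity behaviour, not clinical validity on real radiographs.

## Problem sizes used in the shipped tests

Verification and acceptance runs use the 4×4×3-element compartment at the
51-point stance grid (one full simulation ≈ 30 s), a 20-element
consolidation column, 10-atlas libraries for selection/morphing sweeps,
and a 2-subject/3-atlas end-to-end study at 2×2×2 resolution for the
determinism and concordance checks. These sizes were chosen as the
smallest at which every checked property is resolved; all scale up by
configuration.

## Known limitations

- The stabilization leak couples the undrained limit to the time step
  (see above); fluid conservation is exact only up to the stabilization
  term.
- Anisotropic scaling cannot reproduce shape differences beyond the five
  dimensions; template mismatch shows up as geometry error, exactly as in
  the atlas-based approach it implements.
- The contact fade band (2 mm) slightly softens edge contact at extreme
  flexion.
- Element resolution is deliberately coarse; peak values are
  neighbor-averaged partly to compensate for contact discretization
  artifacts, and absolute peak magnitudes should be read as
  mesh-resolution-dependent.
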