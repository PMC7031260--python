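# Methods

`helixflow` quantifies helical/vortical blood flow in 4D flow MRI velocity
fields by a pressure-based route: rotating flow produces local pressure
minima, so regions of negative *relative* pressure mark helix/vortex cores
more robustly than noise-sensitive local criteria (λ₂, vorticity,
helicity).  This note documents the model, the numerical choices, and what
the synthetic phantoms do and do not establish.

## Units and grids

World coordinates and spacing in mm, velocity in m/s, time in ms, pressure
in mmHg; all conversions happen at I/O boundaries.  A convenient identity:
1 m/s · 1 ms = 1 mm, so pathline displacement needs no unit factor.  Voxel
centers define world positions; the segmentation shares the velocity grid
and nothing is resampled.  Stored axis order is taken as-is (no anatomical
reorientation); an LPS/RAS flag flips only the *reported* handedness
labels.

## Relative pressure map

The pressure gradient comes from the Navier–Stokes momentum balance

    G = −ρ (∂v/∂t + (v·∇)v) + μ ∇²v ,

evaluated with central differences inside the segmentation, one-sided at
the mask boundary, a homogeneous-Neumann discrete Laplacian, and a cyclic
central temporal derivative over the cardiac cycle.  Defaults ρ = 1060
kg/m³ and μ = 4 mPa·s are standard blood values (configurable).

The per-phase relative pressure solves ∇p = G by relaxation on the
face-neighbor graph: every voxel is repeatedly replaced by the mean over
its in-mask face neighbors of `p_j + G_mid·(x_i − x_j)` (midpoint gradient
on the edge).  Two numerical choices matter:

* **Damping.**  The plain sweep does not damp its checkerboard mode; on a
  gradient field with a non-conservative residual (any discrete G is one)
  it enters a limit cycle and never meets the tolerance.  The sweep is
  therefore under-relaxed with ω = 0.8 (ω = 1 restores the plain sweep);
  the fixed point is unchanged.
* **Initialisation.**  Long-wavelength axial modes are the slowest to
  converge; the solve is seeded with the midpoint-rule line integral of G
  along the longest grid axis, after which a uniform axial gradient
  converges in one sweep instead of >10⁴.

Convergence is declared when the largest update is below 1e-6 mmHg
(default), capped at 5000 sweeps per phase with a non-fatal flag.  Each
phase is gauged to zero mean over the mask (relative pressure has no
absolute level).

Post-processing follows the published recipe: one pass of a mask-aware
separable 3×3×3 binomial filter (weights renormalised over in-mask
neighbors, so constants are preserved), winsorisation to the 1–99%
quantile range (linear-interpolation quantiles), and subtraction of the
mean of the filtered values.  Both the quantile bounds and the mean are
taken over **all** masked voxels of **all** phases (a per-phase variant is
switchable); a per-phase mean shift would force negative voxels at every
phase and make the temporal-existence metric trivially 100%.

## Helix regions and parameters

Voxels with P < 0 mmHg (strict) form the helix mask.  Within an
arc-length-bounded ROI the per-phase mask splits into 26-connected
components (helices are oblique); components below `min_component_ml`
(default 0 — every region counts) are dropped.  The temporal union of
retained voxels is the *accumulated* helix.  Parameters:

* **TH_Ex** — dt × number of phases with ≥ 1 component (ms; % of cycle).
* **HV_max** — largest instantaneous helix volume (ml; % of the static ROI
  volume) and its phase.
* **HV_acc** — volume of the accumulated union (ml; %).  Verified against
  a brute-force per-voxel temporal-OR oracle.
* **HVL_acc** — centerline length covered by the accumulated helix (mm; %
  of ROI length, capped at 100).  Each voxel maps to its nearest
  centerline sample and covers its own axial footprint (± half the largest
  voxel edge along the arc); covered-sample weights are summed, so axially
  split helices are not bridged.  Without the footprint, a centerline
  sampled finer than the voxel grid (default 1 mm samples on 2 mm voxels)
  could never have every sample covered and the length would be
  undercounted ~2×.
* **HV(I)** — helix volumes divided by body surface area (ml/m²), DuBois
  by default (`0.007184·W^0.425·H^0.725`; Mosteller switchable) — the
  cardiology convention when the formula is unstated.

## Pathlines and rotation direction

Pathlines integrate the time-varying field with classical RK4 (step
dt/substeps, default 4), trilinear spatial and linear temporal
interpolation, forward from the seed phase to the end of the cycle.  A
line terminates on leaving the mask: outside the lumen the velocity is
undefined, and zero-padding would drag lines along the wall.  Seeding is
voxel-centered in the helix mask (stride 1 = densest; "auto" phase = the
HV_max phase); a helix-fraction filter (default 0.25) keeps lines that
spend enough samples inside the mask.

Handedness uses the published cross-section construction: at the nearest
centerline point с with tangent n, the plane axes are nx = n×(1,0,0)
(normalised; world-y fallback when n ∥ x) and ny = nx×n.  One segment's
label is the sign of the shortest signed angle between its projected
endpoints — a single rule that reproduces all three published quadrant
cases (Q1→Q2 right-handed, Q4→Q3 left-handed, diagonal via the y-axis
crossing), kept as regression tests.  A pathline is RD+/RD− by majority
vote over non-degenerate segments; ties and zero-angular-motion lines are
"indeterminate".  Note the (nx, ny, n) chart is left-handed — that is what
the construction prescribes — so RD+ is clockwise viewed along the flow.

## Flow quantification

A measuring plane orthogonal to the centerline (default mid-ROI) is
sampled at half the smallest voxel edge, clipped by trilinear mask
interpolation ≥ 0.5.  Net forward flow is the signed sum of v·n over lumen
samples and phases (retrograde subtracts); peak velocity is the maximum
speed (through-plane component switchable).

## Phantoms: the stated world

The validation phantom is a straight rigid tube (R 10 mm, L 120 mm, 2 mm
isotropic, 25 phases, dt 40 ms — the scale of an aortic acquisition) with
Poiseuille axial flow and an optional Rankine swirl (core 5 mm, Ω 100
rad/s, |v| ≤ 0.5 m/s, within a 150 cm/s Venc) of known handedness, gated
in time and confined to an axial band.  Rankine is chosen over smoother
vortices because its radial pressure deficit is piecewise closed-form
(−ρΩ²r_c² = −1.988 mmHg at the axis), giving an exact solver oracle.  The
gated recovery phantom carries **no** mean axial flow: a steady Poiseuille
ramp alone puts the downstream half of the tube at P < 0 after mean
subtraction — a documented false-positive mode, pinned by its own test.

What the phantoms do *not* emulate: curved/tapering lumina, wall motion,
partial-volume and segmentation error, spatially correlated MRI noise,
velocity aliasing in-vivo.  Green phantom tests establish numerical
correctness of the operators, not clinical validity.

## Known limitation: strict thresholding of near-zero backgrounds

On hard-gated synthetic fields the strict P < 0 rule is degenerate.  Three
interacting mechanisms, each measured on the default gated phantom:

1. the 1% winsorisation bites the deep negative vortex tail harder than
   the flat positive background, so the subtracted global mean is slightly
   positive (+7.8e-5 mmHg) and every no-flow phase lands uniformly just
   below zero;
2. the hard axial band makes G non-conservative, and its least-squares
   pressure places the far-field plateau at ≈ −3e-4 mmHg even before any
   shift;
3. the cyclic temporal derivative leaks the gate transition into the
   adjacent off phases (±7.5e-3 mmHg structure).

Consequently the end-to-end temporal existence saturates at 100% and the
accumulated helix fills the ROI, although the flagged ON-phase voxels are
three orders of magnitude deeper (−0.7 mmHg) than the spurious background.
The sign in mechanism 1 is geometry-dependent: on a smaller gated phantom
(40 mm tube, 8 phases) the shift comes out negative and the gate is
recovered exactly.  The phase-counting, volume and length semantics are
therefore verified against the generator's ground-truth helix regions,
and the end-to-end gated recovery is left as a failing acceptance test
rather than papered over with an ad-hoc pressure floor.  Real data do not
sit on this knife edge — background pressure variation is orders of
magnitude above machine-level residuals — but any user thresholding
near-noiseless synthetic fields should be aware of it.

## Statistics

Bland–Altman bias ± 1.96·SD (sample SD, conventional multiplier, not the
t-based small-sample variant); Wilcoxon signed-rank via scipy (exact null
for n ≤ 25 without zeros, normal approximation with tie correction
otherwise, Pratt zero handling; all-zero differences return p = 1,
flagged); Pearson correlation ("paired correlation" read as Pearson;
Spearman available through scipy directly); ICC fixed to the two-way
random, absolute-agreement, single-measurement form ICC(2,1) — the
standard two-observer reliability choice — computed from the mean-squares
decomposition and cross-checked against pingouin's ICC(A,1) in the tests.
Zero between-subject variance makes the ICC undefined (flagged, not NaN).

## Interfaces

The package is a library: importable functions plus the narrative scripts
under `examples/`; there is no command-line interface.  Velocity and masks
read from NIfTI (per-component 4D files) or a self-contained HDF5 bundle;
centerlines from CSV (`x_mm,y_mm,z_mm[,arc_mm]`); all results export as
JSON/CSV with units in the key names, and volumetric outputs as NIfTI.
VTK export is intentionally out of scope (no VTK bindings are assumed at
runtime).
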