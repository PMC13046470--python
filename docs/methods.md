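# Methods

## The model

A confined polar fluid describes the coarse-grained cell polarity of
the epiblast: a vector field **p**(r) on the tissue volume Ω with
boundary ∂Ω, penalized by a restoring energy a|p|²/2 (the tissue is in
the isotropic phase, a ≳ 0, so order exists only where boundaries
impose it), splay and bend distortion energies k₀(∇·p)²/2 and
k₂[p̂×(∇×p)]²/2, and a weak-anchoring surface energy w(p−p₀)²/2 that
pulls the boundary value toward a preferred direction p₀.  Normalizing
lengths by R₀ = (3V₀/4π)^{1/3} leaves three dimensionless parameters:

| parameter | meaning | default |
|---|---|---|
| ξ/R₀ = √(k₀/a)/R₀ | correlation length: how far boundary-imposed order propagates inward | scanned, reference 0.2 |
| λ/R₀ = (w/a)/R₀ | anchoring length: boundary preference vs. bulk restoring | scanned, reference 5 |
| K = k₂/k₀ | bend/splay stiffness ratio | 10⁻² |
| \|p₀\| | preferred boundary order | 1 (sets the scale of p) |

The tissue boundary is two spherical caps meeting at an equator: cap α
(the ExE interface, polar angles θ ∈ [0, π/2]) and cap β (the VE
interface, θ ∈ [π/2, π]), each a sphere of radius R_μ centred at
(0, C_μ) on the symmetry axis.  Internally the caps are parameterized
by (R_μ, C_μ); the curvature form (κ_μ = 1/R_μ, γ_μ = 1/C_μ) is exposed
for evaluation but is singular for a cap centred at the origin, which
is a perfectly legitimate shape.  Anchoring is *tangential* on the α
cap (preferred direction along the meridian, oriented from the equator
toward the α apex) and *normal* on the β cap (pointing into the
tissue, the apico-basal direction).  The tangential orientation was
fixed by solving the model both ways: the equator→apex orientation
continues the proximally directed interior flow sourced by the VE-side
anchoring and yields a boundary-trace winding of +1 with a single
interior defect displaced toward the ExE side; the opposite
orientation creates a shear valley along the ExE boundary and total
winding +2, which matches neither the observed +1 charge nor the
single-defect phenomenology.  Both signs remain configurable on
`AnchoringSpec`.

## Axisymmetric finite-element minimization

By symmetry the field is in-plane in a constant-azimuth slice,
p = (p_x, 0, p_z) in cylindrical coordinates, and every integral
carries the measure 2πx dx dz.  Two consequences shape the solver:

* The curl of an axisymmetric in-plane field is purely azimuthal and
  hence perpendicular to p̂, so the bend density reduces *exactly* to
  K(∂p_x/∂z − ∂p_z/∂x)².  No division by |p| survives, the functional
  is a convex quadratic, and the damped Newton iteration (relative
  residual tolerance 10⁻⁶, monotone energy decrease enforced)
  converges in a single sparse SPD solve.  This removes any need to
  regularize p̂ at field zeros.
* Regularity on the axis requires p_x = 0 at x = 0, imposed as an
  essential constraint; the 1/x in the divergence is integrated with a
  strictly interior degree-2 quadrature rule.

The mesh is a structured triangulation in polar coordinates (radial
rings scaled to the local boundary radius), target edge length 0.05 R₀,
with boundary facets tagged by cap.  With smooth (uniform) anchoring
the energy is mesh-converged to ~2·10⁻⁴ between resolutions 0.05 and
0.025.  The heterogeneous tangential rule makes p₀ discontinuous at
the α apex (the meridional tangents of opposite azimuths clash), a
genuine corner singularity at which the energy converges only first
order (~6% / ~3% between successive halvings); field topology, defect
positions and the global order P are stable across these resolutions.
Any P1 discretization of this boundary condition shares the
limitation.

The default Newton initialization is a weak radial field
0.1·(r − r_centre); since the discrete problem is strictly convex the
minimizer is unique and runs are bit-reproducible.

## Defects

Defects are zeros of p with nonzero winding.  A constant-azimuth plane
through the axis is a full plane (its x < 0 half is the opposite
azimuth, where p_x is odd and p_z even), and defects are reported in
that plane, as in the cross-section figures this mirrors: an on-axis
zero appears once; an off-axis zero is a defect *ring* in 3D and
appears at ±x, so the plain sum of indices equals the winding of the
field along the whole tissue boundary (Poincaré–Hopf).  Candidates are
nodal minima of |p| below 0.2·max|p| at least two resolutions from the
boundary (zeros pinned on the boundary are anchoring artifacts); each
candidate gets a small-loop winding (regular minima wind 0 and drop
out), then overlapping candidates are clustered and re-measured with
one enclosing loop, which merges unresolved near-axis ring/saddle
groups into the single defect the experiment would report.  Loops use
64–128 sample points on the mirror-extended linear interpolant;
windings farther than 0.15 from an integer are flagged rather than
counted.

In the surface-dominated regime the total charge is +1 across the
scanned parameter range; the defect-free state (no discernible zeros,
total charge 0) appears at long correlation and weak anchoring.
Decreasing ξ/R₀ at fixed λ/R₀ — the growing embryo outrunning its
correlation length — crosses into the defect-containing state.  The
single defect sits at the domain centre under uniform perpendicular
anchoring and is displaced toward the α (ExE) cap by the heterogeneous
anchoring; positions are reported as (z − L/2)/L with L the axial
tissue extent measured from the distal tip.

## Shape quantification

Cells arrive as an integer label volume with isotropic voxels (µm).
Raw anisotropic stacks are channel-summed, 2×2×1 binned and rescaled
to cubic voxels first.  Each label becomes a marching-cubes surface at
the physical scale, repaired to consistent outward orientation; the
whole-tissue mesh keeps its largest connected component and stores the
nearest cell label per vertex.  Solid-body inertia comes from the
closed mesh (trimesh volume integrals); the spectrum λ₁ ≤ λ₂ ≤ λ₃
gives the anisotropy η = (λ₃ − √(λ₁λ₂))/λ₃ (0 for spheres, → 1 for
needles).  The cell's long geometric axis is the principal direction
of the *smallest* inertia component — for a prolate body the two large
components are degenerate and their eigenvectors are transverse, so
this is the only well-defined "major axis".  Polarity is that axis
sign-fixed outward (toward the boundary normal for boundary cells,
away from the tissue centroid for interior cells; an exactly
perpendicular axis keeps its sign), and the cell-boundary angle is
arccos|p̂·n̂| in degrees: 0° means the cell stands perpendicular to the
boundary surface, 90° lies parallel.

Boundary normals average the tissue-mesh vertex normals over the
cell's surface patch with dual-area weights.  The weighting matters:
marching-cubes surfaces carry more vertices where the surface runs
oblique to the voxel grid, and an unweighted vertex mean inherits a
grid-orientation bias of several degrees; the area-weighted mean is
the orientation-unbiased estimator of the same quantity and is what
makes the pipeline rotation-equivariant to below 2°.

Neighbour relations use a one-voxel 26-connected dilation; pairs
overlapping less than 20 µm³ are discarded, and each unordered pair is
reported once with the inter-axis angle folded to [0°, 90°].

## Nematic averaging

The distal–proximal frame comes from annotation points: a rotation
axis through the tissue centroid and the distal tip, a 0° rotation
plane through the mean transverse-edge point, and a least-squares
interface plane retained to split the boundary into its α and β parts.
Coordinates are rescaled to unit tissue volume.  M = 36 rotational
slices are rotated into the x–z plane, carrying the elongation axes
v′ = η·v of the cells they intersect, and the weighted Q tensor

Q(r) = (1/M) Σ_m ‖v″_m‖ ( (3/2)·v″v″ᵀ/‖v″‖² − I/2 )

is accumulated on a uniform grid (64×64 default; a fixed shared grid
for cohorts).  Empty slices contribute zero but still count in the
1/M, as the formula states — this deliberately dilutes Λ near the
tissue surface where a grid point is only covered in part of the
slices, and is the reason comparison points keep a margin from the
boundary.  The principal eigenvector is the unsigned director
(reported with V_z ≥ 0, ties broken by V_x ≥ 0; flagged NaN when the
top eigenvalue is degenerate), the eigenvalue Λ the local strength,
and Λ_avg the cylindrical-measure volume average of Λ/Λ_max over the
region enclosed by the rotationally averaged boundary.  Cohort maps
average the Q tensors (never the directors) before
eigen-decomposition.  Λ_max is the maximum strength over the whole
cohort and all positions.

The averaged boundary intersects the tissue mesh with each slice
plane, folds to x ≥ 0, resamples in polar angle and averages radii
over slices.  The margin d used to exclude low-statistics regions is
the mean standard deviation *across embryos* of their averaged
curves — embryo-to-embryo shape variability, not the within-embryo
lumpiness of the cellular surface, which is an order of magnitude
larger and would not shrink with cohort size.  For single synthetic
embryos d defaults to the per-slice spread.

## Material-length inference

The measured polarity magnitude is p_exp = Λ/Λ_max.  The global
experimental order P_exp is its cylindrical-measure average over the
enclosed region — the x-weight in the integrand implies the
cylindrical normalizer ∫x dz dx, the only reading commensurable with
the model's P = ∫|p|dV/V₀.  The averaged boundary is fitted with the
two-cap profile (split at the interface height, equator continuity
enforced to 10⁻⁸ by penalty continuation from algebraic circle-fit
initial guesses), all coordinates are rescaled by the fitted R₀, and
the cost C(ξ/R₀, λ/R₀) = Σᵢ [p(rᵢ) − p_exp(rᵢ)]² is minimized by
exhaustive search on log-spaced grids (defaults: 12 points ξ/R₀ ∈
[0.05, 1], 16 points λ/R₀ ∈ [0.1, 20], chosen to span both sides of
the defect transition).  Comparison points lie in both shapes, more
than 0.05 from the axis and more than d from any boundary.  Model
magnitudes are read through a fixed barycentric interpolator on the
shared mesh, so the surface is bit-reproducible and many measured
fields can be fitted against one set of 192 solves.  Directional
information never enters the fit; it validates it afterwards through
|cos∠(p, p_exp)| (sign-free, as the nematic data demand) and through
|p·x̂| / |p·ẑ| profiles along three horizontal paths at t/4, t/2, 3t/4
above the distal tip and three vertical paths at w/6, w/3, 2w/3 from
the axis, in path-rescaled coordinates.

## Synthetic embryos

The generator renders what the analysis consumes: a two-cap tissue
(default R₀ ≈ 22 µm) with n cells (default 60, within the observed
15–115 range), isotropic voxels (default 0.8 µm; the imaging data this
emulates are finer, 0.16–0.35 µm, and tests sensitive to discretization
use 0.4–0.6 µm), cell centres placed by dart throwing with a minimum
separation, long axes drawn from an orientation rule — radial,
isotropic, a boundary-anchored composite, or a solved polarity field —
with von Mises–Fisher concentration κ (default 20), and prolate
semi-axes inverted from a target anisotropy via
(a/b)² = 2/(1−η)² − 1 (η uniform in [0.2, 0.8] by default; for
field-driven embryos η is proportional to the local |p|, so the
pipeline's normalized nematic strength reproduces the field magnitude
up to one scale).  Voxels are assigned to the cell with the smallest
normalized ellipsoidal quadratic form, which keeps overlapping cells
disjoint; by default every in-domain voxel is claimed (anisotropic
Voronoi tiling), the gap-free structure membrane segmentation of an
epithelium actually produces and the reason the tissue surface is
smooth.  Annotations are the points a human would click: interface
points on the equator circle, the distal tip, two transverse-edge
points, with optional jitter.  Everything is seed-deterministic, and a
whole-embryo rigid rotation can be applied for equivariance studies.

What the synthetic data do *not* emulate: curved or irregular cell
shapes beyond truncated ellipsoids, segmentation errors other than
label dropout, intensity channels, and real biological variability of
η with position.  Two measurement biases are intrinsic and documented
rather than hidden:

* *Voronoi shape floor.*  Tiled cells inherit an anisotropy of ~0.2
  from their polyhedral shape even when the seed ellipsoid is a
  sphere, so the measured p_exp of weakly ordered regions is inflated
  under tiling.  The field-recovery closure therefore renders exact
  ellipsoids (no tiling).
* *Cell-footprint smearing.*  Each cell reports the field at its
  centre over its whole footprint.  At tissue-realistic cell numbers
  (~60) this inflates the recovered correlation length by roughly a
  factor two (about two cells of the log-spaced search grid); with 250
  cells per embryo the full pipeline recovers the generating
  (ξ/R₀, λ/R₀) within one grid cell.  The closure tests run at the
  dense setting; the analysis scripts run at the realistic setting and
  say so.

## Problem sizes

The test suite and analysis scripts run at: FEM resolution 0.05 R₀
(~1300 nodes, milliseconds per solve), phase diagrams up to 12×16
parameter pairs, cohorts of 4 embryos with 60–250 cells at 0.6–0.8 µm
voxels (~80³–130³ labels), 36 rotational slices on 48–64² grids, and
Monte-Carlo oracles of 10⁵–10⁶ samples.
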