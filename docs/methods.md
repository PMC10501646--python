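# Methods

This note describes the models and numerical procedures implemented in
`brocamorph`, the assumptions behind them, the parameters that matter,
and what the synthetic data generator does and does not emulate.

## Surface representation

A cortical hemisphere is a closed triangle mesh in mm with a one-to-one
spherical parameterization carried per vertex (`sphere_coords`). All
registration happens on the unit sphere; all measurement (areas,
volumes) happens on the anatomical mesh. Synthetic meshes are born on an
icosphere, so their parameterization is exact by construction; for real
data the parameterization would come from the usual inflation-to-sphere
step of a surface pipeline, upstream of this package.

Vertex areas follow the barycentric rule — each face assigns one third
of its area to each corner. The rule is exactly conservative (vertex
areas sum to the total surface area to rounding), which the Voronoi rule
is not in the presence of obtuse triangles. Regional volume is the prism
approximation Σ A_v t_v: the region's surface area weighted by local
cortical thickness. No distinction is made between white, pial, or
mid-thickness surfaces; measurements apply to whatever single surface is
supplied, identified by its `space_tag`.

### Sulcal depth

The depth map drives nonrigid registration. It is computed by iterated
umbrella-Laplacian smoothing (defaults: 50 iterations, step 0.5): each
vertex's accumulated displacement is projected on its original outward
normal, so sulcal fundi (which move outward while the surface smooths)
get positive depth and gyral crowns negative. Two details matter
numerically:

* the umbrella operator also shrinks any curved discrete surface by an
  amount that depends on vertex valence, not on folding; the identical
  iteration is therefore run on a radius-matched reference sphere with
  the same connectivity and subtracted step by step. A perfect sphere
  consequently accumulates exactly zero depth;
* the result is z-scored over vertices, making depth comparable between
  meshes of different size; a constant raw map (sphere) z-scores to all
  zeros rather than dividing by zero.

Synthetic templates use the analytic depth (z-scored negative radial
bump) rather than the smoothing estimate; the smoothing implementation
is exercised by its own tests (sign of a dimple, rotation invariance).

## Synthetic two-species populations

The generator provides what real cross-species data cannot: a known
correspondence and known effect sizes.

* **Template.** Icosphere at subdivision 5 (10,242 vertices; chosen so a
  boundary ring of the BA44-analog patch is ~15% of its area, fine
  enough for the statistics below while keeping the full pipeline in
  seconds per registration). Radius 40 mm for the chimpanzee analog,
  55 mm for the human analog. Radial perturbation is a sum of 12
  von-Mises-like bumps `a_k exp(κ_k(u·d_k − 1))` with κ ∈ (8, 40) and
  amplitude 2.5 mm (3.2 mm for the larger species) — a gyrification
  analog with smooth, registration-friendly depth structure. Thickness
  is an independent smooth field, mean 2.5 mm, sd 0.3 mm, clipped at
  0.5 mm; both species default to the same thickness distribution so
  cross-species volume ratios are label-driven unless a difference is
  requested.
* **Labels.** Two region patches (BA44/BA45 analogs, area fractions
  0.05/0.04 of the hemisphere) plus a landmark patch (inferior frontal
  gyrus analog, fraction 0.12) used only for coarse alignment. Patches
  are grown by sorted (optionally anisotropic) angular distance from a
  seed direction until the target area is reached — equivalent to
  breadth-first geodesic growth for convex patches but controllable to
  vertex granularity. Regions are grown first and the landmark around
  them, matching the anatomy (the IFG contains the regions); region
  jitter and expansion may claim landmark territory but never another
  region's.
* **Subjects.** Each of the default nine subjects (the retained sample
  size of the motivating study) is the template composed with a random
  smooth tangential warp (six bump components, maximum displacement
  0.05 rad ≈ 2 mesh edges at subdivision 5 — comfortably inside the
  fold-rejection limit, and large enough that registration must do real
  work). Fields and labels are resampled through the warp; labels are
  then eroded/dilated by a uniform number of boundary rings in
  {−j, …, +j} (default j = 1), a simple, area-controllable stand-in for
  histological delineation variability. Hemisphere pairs are mirror
  images with independent jitter; a known asymmetry enters only through
  `left_area_inflation`, which rescales left-hemisphere target areas
  before jitter. Because dilation is blocked where a region abuts its
  neighbor while erosion is not, jittered areas run slightly below the
  template patch on average; this biases the end-to-end expansion
  estimate high by a few percent, well inside its tolerance.
* **Species pair.** Species B's folding is species A's pulled through a
  known smooth warp (amplitude 0.06 rad), plus an independent component
  at 20% relative amplitude (`depth_divergence`) emulating
  lineage-specific folding — so cross-species registration is solvable
  but not trivial. B's first region contains the warped image of A's
  region as a core and is grown to `expansion` (default 1.6) times the
  core's area, preferentially along a fixed anterior tangent displaced
  by `shift_deg` (default 20°) with elongation 1.8. The recorded ground
  truth expansion is the built region's area fraction over the
  true-warp transfer's area fraction: the species warp does not
  preserve area, so this — not the raw cross-species fraction ratio —
  is the quantity a perfect pipeline would estimate.

**What the generator does not emulate:** realistic cortical folding
statistics (no sulcal branching, no species-specific folding patterns
beyond smooth bumps), MRI intensity or reconstruction error, topological
defects, and any thickness–folding covariance. Tests passing on this
generator show the pipeline's machinery is correct and well-calibrated
under known conditions; they do not certify accuracy on real
histological data, where delineation error is not ring-shaped and
cross-species correspondence is not smooth.

## Volume ↔ surface label transfer

Rasterization labels every voxel whose center lies within half the local
thickness of a labeled vertex (nearest labeled vertex among four
candidates). Projection ribbon-samples the volume at `n_samples` = 5
points spaced evenly along the vertex normal within ± thickness/2,
looks each up by nearest voxel (labels are categorical; interpolation
would invent mixtures), and takes the majority non-background label.
Ties break to the sample nearest the vertex, then to the smallest label
id — fully deterministic. Round trips at voxel size 0.5× the mean edge
length achieve Dice ≥ 0.95 on the region patches, and fidelity decays
monotonically as voxels coarsen.

## Registration

### Coarse stage

A rigid rotation solved as a weighted orthogonal Procrustes problem on
matched unit directions: the area-weighted landmark-patch centroid
(weight 2) plus the whole-surface centroids weighted by the positive
(sulcal) and negative (gyral) parts of the depth map (weight 1 each).
The two depth centroids were chosen over a single depth-weighted
centroid because the latter, once shifted non-negative, is dominated by
its constant part and lands nearly collinear with the landmark centroid,
leaving the roll about the landmark axis ill-determined; the split
centroids are well-separated and stable across subjects. If no usable
secondary direction exists (featureless sphere), only the centroids are
aligned, with a warning; exactly antipodal centroids rotate by π about
an arbitrary perpendicular.

### Fine stage

The nonrigid energy is the area-weighted SSD of z-scored depth plus a
graph-Laplacian penalty on control-vertex displacement differences
(λ default 0.1, selected by synthetic recovery experiments). The
optimization is coarse-to-fine over icosphere control grids (levels 3,
4, 5 by default), with three numerical devices:

1. **Rigid sub-stage.** Before the nonrigid levels, a three-parameter
   global rotation is optimized against the same energy on heavily
   smoothed maps (Newton steps with backtracking). Featureless regions
   carry no depth gradient, so a global rotation left to the nonrigid
   stage would be reconstructed there by harmonic interpolation, which
   a rotation field is not; fitting the rotation explicitly removes
   that bias (known-rotation recovery is exact rather than ≈1°).
2. **Coarse-level smoothing.** At control level ℓ below the finest, both
   depth maps are smoothed by 4^(top−ℓ) neighbor-averaging passes, in
   proportion to control spacing, so coarse levels see a wide, smooth
   basin; the finest level uses the raw maps.
3. **Gauss–Newton steps.** Each iteration solves
   (JᵀJ + λL) d = −∇E approximately by Jacobi-preconditioned conjugate
   gradients (≤ 40 iterations), then line-searches along d with
   backtracking from the full step. Steps are accepted only if the
   objective strictly decreases *and* no spherical triangle flips
   orientation; a level stops at relative decrease < 1e−5 or 100
   iterations. The objective trace per stage is stored in
   `warp.info["objective_traces"]` and asserted non-increasing in tests.

Warps store forward maps (one target-sphere point per source vertex).
Pulling data onto target vertices locates each one inside the warped
source triangulation using gnomonic (central-projection) barycentric
coordinates, which reproduce the query direction exactly after
normalization; composition of warps interpolates the second warp at the
first's targets, and is exact to floating point for rotations. Points
that land in no candidate triangle (numerically) fall back to their
nearest vertex. Scalar maps travel by barycentric interpolation
(probabilities re-clipped to [0, 1]), label maps by nearest-vertex
transfer.

With the large-λ limit the *nonrigid* displacement vanishes and the
result reduces to the (rigidly refined) initialization; the rigid
component is deliberately outside the smoothness penalty, since a global
rotation of the sphere is not a deformation.

## Atlas and statistics

The probabilistic atlas is the per-vertex frequency of a region across
registered subjects; attainable values are multiples of 1/n.
Thresholding uses ≥, so t = 0 labels everything; with the default nine
subjects the 0.5 level itself is unattainable (frequencies are ninths)
and the boundary convention is inert.

The Wilcoxon signed-rank test drops zero differences, midranks ties, and
reports T = min(W⁺, W⁻). For untied samples with n ≤ 25 the two-sided
p-value is exact: p = min(1, 2·P(W ≤ T)) under the null distribution of
rank sums, computed by the standard polynomial recursion (identical to
enumerating all 2ⁿ sign assignments; the test suite checks this against
a literal enumeration oracle for n ≤ 10 and against scipy's exact mode).
With ties, exact enumeration is invalid under midranks and a normal
approximation with continuity and tie corrections is used instead. At
n = 9, T = 16 the exact p is 254/512 ≈ 0.496; published accounts print
0.49, a final-digit rounding difference this package documents and does
not chase.

Calibration on synthetic populations (nine subjects, ring jitter, no
geometric warp — the test consumes areas only): empirical type-I error
≈ 5% at the nominal 5% level, and power ≈ 84% against a 1.3-fold
left-area inflation, each over 100 seeded populations. The discreteness
of ring jitter makes the test mildly conservative.

## Cross-species comparison

Per-subject regions are composed through subject→templateA→templateB
warps and measured on template B with B's thickness — "scaled up and
projected" to the target species, so they are directly comparable with
volumes reported for that species. The expansion factor is
reference_mean / projected_mean; the across-subject SD uses the n−1
denominator (one subject reports no SD). Reference volumes may be
supplied as published constants instead of recomputed, mirroring how
published human means are used against projected homolog volumes.
Containment is area-weighted by default (vertex counts behind a flag for
sensitivity), and the threshold sweep is non-increasing in the threshold
by set inclusion.

End-to-end on the default synthetic conditions (expansion 1.6, shift
20°, nine subjects, default registration), the pipeline recovers the
expansion factor typically within ten percent (tolerance ±15%; the
spread is dominated by cross-species registration error under the
lineage-divergent folding component, plus the small upward jitter-area
bias), and the part of B's region not covered by the projected homolog
lies predominantly on the anterior side of the shift axis.

## Degenerate inputs and numerical conventions

Zero-area faces contribute nothing to vertex areas (with a warning);
empty landmark patches, all-zero paired differences, empty functional
regions, zero projected volumes, non-invertible affines, and
orientation-flipping warp amplitudes all raise errors rather than
returning garbage. Voxel indices are 0-based with the affine mapping
indices to world mm (NIfTI convention). All randomness flows through
`numpy.random.default_rng` seeds carried in the spec objects; identical
seeds give bit-identical outputs, and every CLI report embeds the seed
and a configuration hash.

## Known limitations

* The prism volume approximation ignores curvature; it is the
  convention here, not an estimate of the true cortical ribbon volume.
* Registration guarantees no flipped spherical triangles but is not
  diffeomorphic in any stronger sense, and uses a single similarity
  channel (sulcal depth).
* Geodesic quantities use graph/angular approximations, not exact
  polyhedral geodesics.
* The containment analysis reports overlap fractions only; it does not
  model uncertainty in either region's boundary.
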