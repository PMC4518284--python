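# Methods

## Scope and model

`vasculometry` quantifies the 3D architecture of contrast-perfused
microvasculature in high-resolution micro-CT volumes of the spinal cord
(or comparable tubular networks).  The analysis contract is the classic
vessel-tree model:

* the binary vasculature is obtained by an iterative gray-level threshold
  followed by a 3D size filter;
* centerlines are extracted by topology-preserving thinning;
* a Euclidean distance map (EDM) gives every vessel voxel its distance to
  the nearest background voxel, and the product of skeleton and EDM gives
  per-centerline-voxel radii;
* the skeleton is converted to a graph of nodes (endpoints, bifurcations)
  and segments, from which the morphometric quantities are computed:
  **VV** (vessel volume: fractional occupancy of an ROI and mm³),
  **VN** (vessel number: segments between two nodes),
  **VNN** (vessel node number: bifurcation count),
  **L** (segment length), **VD** (vessel diameter: twice the mean
  centerline radius along a segment), and **θ** (signed intersection
  angle between a branch and the rostrally oriented trunk axis — the
  anterior-spinal-artery axis in cord data: positive ≤ 90° pointing
  rostrally, negative pointing caudally);
* groups are compared metric-by-metric with the pooled two-sided
  Student's *t*-test, reported as mean ± SD.

Because no real scan data ship with the package, a synthetic phantom
module generates volumes with exactly known ground truth; every pipeline
stage is validated against that truth or against independent brute-force
oracles.

## Segmentation

The threshold is the Ridler–Calvard (isodata) fixed point: starting from
the global mean, `T ← (mean(I ≤ T) + mean(I > T)) / 2` until the update
falls below a tolerance (0.5 gray values for integer data, 10⁻⁴ of the
intensity range for float data — this guarantees termination on quantised
images).  Binarisation is strict (`I > T`).  The size filter removes
foreground components and fills background holes *smaller than* a minimum
count (default 3 voxels, read strictly: 3-voxel components survive),
using 26-connectivity for foreground and 6-connectivity for background —
the standard dual pairing.  The filter is idempotent.

Isodata has a known failure mode on very sparse foregrounds: when the
vessel class is a small fraction of the histogram, a second fixed point
exists that splits the *background noise* in half.  Measured on 128³
phantom volumes with 150 gray values of vessel/background contrast: at a
foreground fraction of ~1.5 % the iteration stays in the correct basin
for noise σ ≤ 12 but collapses at σ ≥ 15 (33 % of voxels misclassified);
at ~5 % foreground the boundary moves to σ ≈ 20, and at ~8 % to σ ≈ 25.
The working range of the unmodified threshold+filter pipeline is
therefore a contrast-to-noise ratio of roughly ≥ 10 at capillary-scale
sparsity.  This is a property of the method itself, faithfully
reproduced; no re-initialisation heuristics are added.

## Skeletonization and radii

Thinning uses Lee's 6-subiteration border-point removal (direction order
U, D, N, S, E, W, via scikit-image), which preserves 26-connectivity and
tunnels.  One guard is added: sequential thinning can annihilate a
perfectly mirror-symmetric, even-width contractible object outright (its
correct skeleton is a single point).  Any input component with no
surviving skeleton voxel is therefore restored as its single deepest
voxel (maximal EDM, raster order breaking ties), keeping the component
count exactly invariant.  No spur pruning is applied by default
(`prune_length_um = 0`); a length-based pruner is available.

The EDM is the exact Euclidean transform (scipy), honouring anisotropic
spacing; a (3,4,5)/3 chamfer variant is available behind a `chamfer`
flag for comparison with chamfer-based toolchains.  Thinning itself
operates on the voxel grid and ignores spacing (a documented limitation);
distances and lengths honour it.

## Graph extraction

Skeleton voxels are classified by 26-neighbour count (1 endpoint, 2
slab, ≥ 3 junction).  Adjacent junction voxels are merged into one node
(thinning produces junction *clusters*; per-voxel counting would inflate
VNN).  Segments are traced through slab runs between nodes; node-free
cycles are traced as single cyclic segments and flag the graph.  Segment
length is the sum of physical inter-voxel steps.  VD is twice the
trimmed mean radius: for segments longer than 6 voxels the 2 voxels
nearest each node are excluded, because the EDM there reflects the
junction pocket, not the branch calibre.  Endpoint-to-junction segments
count toward VN by default (`include_endpoint_segments` restricts to
junction–junction segments); segments touching an ROI boundary are
counted, with no edge correction.

**Branch angles.**  The direction of a branch at a junction is a
principal-axis fit of `k = 5` skeleton voxels pointing away from the
node.  The fit window starts one junction radius (the maximum EDM value
over the junction cluster) beyond the node whenever the branch is long
enough, falling back to the voxels immediately after the junction for
short branches.  The skip matters: immediately past a junction the
centerline still curves from the parent vessel into the branch, and a
fit anchored there underestimates steep angles by up to ~20° at thick
junctions.  With the offset window, recovery error on rasterized test
branches (radius ≥ 2 voxels) is ≤ 3.3° across 15°–90°.  θ is signed by
the rostro-caudal convention above.

## The phantom generator

The generator emulates the blood-supply pattern seen in cord
angiography: a longitudinal trunk (the central/anterior axis) running
along z (+z = rostral), branching into a complete binary tree of
`branch_levels` generations.  Defaults (one 128³ volume at 3.7 µm
isotropic — the pixel scale of the emulated detector):

| parameter | default | meaning |
|---|---|---|
| `trunk_radius_um` | 37 | trunk radius (diameter 74 µm ≈ the largest cord vessels) |
| `branch_levels` | 2 | 1 + 2 + 4 = 7 segments, 3 bifurcations |
| `branch_angle_deg` | 68 | nominal parent–child angle (the normal central-sulcal-artery angle) |
| `jitter_deg` | ±5 | seeded angular jitter; keeps geometry non-degenerate |
| `taper_ratio` | 0.7 | child/parent radius |
| `radius_range_um` | [3.7, 50] | admissible radii: diameters 7.4–100 µm |
| `foreground/background` | 200 / 50 | gray values |
| `blur_sigma_um` | 1.85 | partial-volume blur (½ voxel) |
| `noise_sigma` | 12 | additive Gaussian noise (CNR 12.5) |

Rasterization marks a voxel foreground iff its centre lies **strictly**
within one radius of a segment centerline (exact point-to-segment
distance — a clean oracle, no sphere-sweeping).  The strict boundary
makes a tube of radius exactly one voxel rasterize to a single-voxel
line whose measured diameter is 2 voxels = 7.4 µm at 3.7 µm spacing, the
detection floor of the emulated instrument; with a non-strict boundary
the same tube would rasterize to a 5-voxel cross and report 10.5 µm.
The trunk axis is snapped onto a voxel-centre column to avoid the
mirror-symmetric degenerate case of sequential thinning noted above.

Degradation is Gaussian blur followed by seeded additive Gaussian white
noise, clipped to [0, 255].  The noise default was calibrated once
against the pipeline's invariance tests (no instrument noise statistics
exist to copy): σ = 12 is the largest white-noise level at which the
isodata basin is stable at the default tree's ~1.5 % foreground fraction
— see the segmentation section.  Real reconstructions differ in ways the
phantom does not model: correlated (streak) noise, beam-hardening and
ring artifacts, intensity inhomogeneity along the contrast column, and
non-tubular background texture.  Passing phantom tests therefore
demonstrates the correctness of the measurement chain, not robustness to
every real-world artifact.

**Injury model.**  A prolate ellipsoidal cavity (axial semi-axis ≥
transverse — the long spindle-shaped avascular lesion) removes vessels:
the volume is carved, ground-truth segments fully inside are deleted and
crossing segments are truncated at the cavity wall with new endpoint
nodes.  Branch subtrees originating within `tilt_extent_um` of the
epicenter are additionally rotated rigidly about their origin — rostral
of the epicenter toward the rostral orientation, caudal toward caudal —
and the volume is re-rasterized from the tilted ground truth rather than
warped, keeping graph and image exactly consistent.  Enlarging the
cavity can only remove foreground (monotonicity), so VV, VN and VNN of
injured phantoms are never above the matched normal ones.

## Statistics

Group summaries are mean ± sample SD (n−1).  The default test is the
pooled-variance two-sided Student's *t* (df = n₁+n₂−2), with Welch's
variant behind a flag; p-values come from the *t* distribution.  Zero
pooled variance with equal means returns t = 0, p = 1; with unequal
means the test is undefined and raises.  No multiple-testing correction
is applied across the three metrics — this mirrors the reporting
convention the module implements and is a documented limitation.

## Problem sizes and numerical choices

The validation suite uses 128³ phantoms for topology recovery (one
noise-free volume plus 20 noisy replicates; 5 + 5 for the injury
comparison), ≤ 20³ grids for the 50 brute-force distance-map
comparisons, 96³ for angle recovery, and 500 simulations for the type-I
error of the *t*-test.  These sizes keep a full run on one CPU in the
minutes range while leaving every quantity measurable at the stated
tolerances.  Ties and degenerate inputs are handled explicitly:
isolated skeleton voxels are endpoints (logged); a slab voxel bridging
two voxels of the same junction cluster is a rasterization artifact and
is not emitted as a self-loop; constant volumes have no threshold and
raise; empty ROIs raise; an all-foreground mask has no defined distance
map and raises.

## Known limitations

* Isodata thresholding fails below CNR ≈ 10 at capillary-scale
  foreground fractions (see above); the pipeline reports what the
  method yields and does not attempt rescue heuristics.
* Junction clusters are merged by 26-adjacency only; junctions closer
  than ~2 voxels apart on the skeleton remain distinct nodes.
* VD near junctions relies on trimming rather than geometric
  reconstruction; very short segments (≤ 6 voxels) are untrimmed and
  their VD is biased upward by the junction pocket.
* Anisotropic volumes are thinned on the voxel grid; strongly
  anisotropic spacing will bias centerline placement.
* The phantom's noise model is white and Gaussian; no correlated CT
  artifacts are simulated.
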