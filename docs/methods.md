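# Methods

This note documents the models, algorithms, parameters and design choices
implemented in gradparc, and what the synthetic test battery does and does
not demonstrate.

## Surface substrate

All computations run on a 2-manifold triangle mesh with a spherical mapping
of fixed radius (100 mm, the FreeSurfer-style convention, configurable), so
that Hausdorff and smoothing distances are in millimetres. Medial-wall
vertices carry NaN in every scalar map — never zero — so they cannot
silently enter an average; operations either skip them or renormalize over
defined vertices.

Geodesic distances are great-circle distances on the sphere. Surface
Gaussian smoothing uses weights `exp(-d²/2σ²)` truncated at `3σ` via a
k-ring cutoff. The kernel is symmetrized to doubly stochastic (Sinkhorn
balancing, tolerance 1e-13): this keeps constant maps fixed *and* preserves
the cortical mean exactly, which a plain row-normalized kernel on an
irregular mesh does not. The medial wall is an identity block, so no weight
crosses the wall.

### Resolution-matched smoothing

The canonical time-course smoothing is σ = 2.55 mm on an acquisition-scale
surface whose vertices are ~2 mm apart, i.e. the kernel spans ≈1.3 edge
lengths. On the coarse synthetic spheres used for testing (15 mm edges at
642 vertices) a 2.55 mm kernel is a no-op, so the pipeline helper
`equivalent_smoothing_sigma(mesh) = (2.55 / 2.0) × mean edge length`
preserves the kernel-to-resolution ratio. This step matters beyond
denoising: spatially correlated vertex noise has far fewer spurious 3-ring
local minima, which is what keeps watershed basins one-per-area. Without
it, planted-parcel recovery on the synthetic cohort saturates around
ARI ≈ 0.6 no matter how many subjects are averaged; with it, recovery is
ARI ≈ 0.9–0.95.

## Connectivity

Pearson correlations are computed by row standardization and matrix
products; zero-variance time courses (outside the medial wall) make the
correlation undefined and propagate as NaN rows/columns, tracked
explicitly. Fisher's r-to-z clips |r| = 1 to 1 − 1e-7 so z stays finite
while preserving order. Second-order connectivity correlates z-profiles
over the columns defined in every valid row (medial-wall columns drop out)
and is row-blocked so a 32k-vertex hemisphere is feasible in memory;
tests run at V ≤ 2562.

Scans of the same visit can be pooled at two stages: averaging RSFC-2nd
matrices before the gradient step (the default), or averaging the per-scan
local gradient maps afterwards (set
`PipelineConfig(average_rsfc2_within_visit=False)`). Both hooks exist
because the two orderings are genuinely different conventions; for
single-scan visits they coincide (asserted in the tests).

## Gradient and watershed

The surface gradient of a per-vertex field is the exact gradient of the
linear interpolant on each triangle (solved in an orthonormal basis of the
triangle plane), with magnitudes area-averaged to vertices; triangles
touching the medial wall are excluded, and degenerate (zero-area) triangles
are an error naming the triangle. Gradient magnitude is invariant to adding
a constant and nonnegative by construction.

Watershed rules, shared verbatim by per-row boundary mapping and group-map
parcellation:

* **Seeds** — local minima of the 3-ring neighborhood. Ties are resolved at
  the level of *plateaus* (maximal edge-connected equal-value sets): a
  plateau seeds iff its 3-ring contains no strictly lower value, and its
  lowest-index vertex represents it. Equal values that are not
  edge-connected to the plateau belong to other basins and do not veto, so
  a constant map yields exactly one region per connected component and an
  empty boundary.
* **Flooding** — one priority queue over (value, vertex index): globally
  ascending, deterministic ties. A popped vertex adjacent to exactly one
  labeled region joins it; adjacent to two or more, it becomes boundary
  (label 0) and never propagates.

The production flood kernel is numba-compiled (array-based binary heap)
with an identical pure-Python fallback; an independent O(V²) linear-scan
oracle exists only in the test suite and the two agree exactly on random
and deliberately quantized (plateau-rich) fields.

The local gradient map of a scan averages its V binary boundary maps.
Group maps are unweighted hierarchical means — phase encodings → session →
visit → age group → age-independent — with **no smoothing** at any pooling
step, so each unit at the pooled level contributes equally.

## Spherical registration

A deliberately simple demons-style registration aligns feature maps (local
FC gradient, optionally folding channels with configurable weights) by
moving each vertex's sphere position:

* force per channel: `(template − warped) · ∇warped / (|∇|² + diff² + ε)`
  (bounded demons normalization), tangent-projected;
* "fluid" smoothing of each update (spherical Gaussian, default σ = 6 mm)
  and "diffusion" smoothing of the accumulated displacement (σ = 4 mm);
  30 inner iterations over 3 coarse-to-fine levels implemented as a
  step-size/fluid-σ schedule on the full mesh (×4, ×2, ×1) rather than
  mesh coarsening, so arbitrary sphere meshes are accepted;
* a line search accepts only steps that decrease the weighted feature MSE,
  so the returned warp never does worse than the identity, and any step
  that would invert a spherical triangle (sign change of the vertex triple
  product) is halved until none does — a cheap diffeomorphism proxy.

Resampling uses barycentric interpolation by central projection with
clipped, renormalized weights (hence convex: constants are invariant and
outputs bounded by the input range); candidate triangles come from a
KD-tree over mesh vertices. Vertices that momentarily sample undefined
territory (the medial wall) exert no force.

The group template iterates register → resample → re-average, 4 outer
iterations by default, stopping early when the mean map changes by less
than 1e-4 anywhere.

**Resolution caveat.** Registration sharpens the group map (the
individual-then-register contrast) only when inter-subject misalignment
exceeds the mesh resolution. On a 642-vertex sphere the edge length is
≈8.6°, so a ≤5° misalignment cannot displace watershed ridges: the naive
mean is already at its sharpness ceiling and interpolation can only lose
peak mass. The property is therefore demonstrated with supra-resolution
rotations (8–20°), where the registered template's peak clearly exceeds the
naive mean's; the MSE-halving property holds at all tested magnitudes. At
acquisition scale (32k vertices, ~1.1° edges) a 5° misalignment spans
several edges, so both effects coexist there.

## Parcellation bookkeeping

Parcels are edge-connected, densely numbered 1..n; borders and the medial
wall are label 0 (an optional post-hoc `fill_borders` assigns each border
vertex to the adjacent parcel with the lower mean gradient, off by
default). Merging over-segmented regions is an explicit merge list —
(id set, surviving id) pairs, validated for adjacency-connectivity — never
an automatic detector, since over-segmentation has no algorithmic
criterion; borders that only separated merged parcels are absorbed into
the survivor.

## Evaluation battery

* **Reproducibility** — random disjoint half-cohorts, each half's mean map
  binarized to its top 25% (exactly ⌈frac·N⌉ vertices, ties by vertex
  index), Dice overlap, 1000 repetitions by default; two empty sets have
  Dice 1 by convention.
* **Homogeneity** — covariance PCA (mean-centered profiles) per parcel;
  value = 100·λ₁/Σλ. Single-vertex parcels are 100 by convention and
  flagged.
* **Variance** — per parcel, the sum over profile dimensions of the
  population standard deviation (ddof = 0) across the parcel's vertices;
  map-level value is the mean over parcels; single-vertex parcels are 0.
* **Rotation nulls** — each null applies one rigid rotation with three
  independent angles uniform on [0, 2π) about x, y, z (in that order) and
  resamples labels to the nearest vertex, preserving parcel count and (up
  to resampling) sizes; a parcel with ≥50% of its vertices landing on the
  medial wall (configurable) is flagged and skipped in that null, and its
  summary is averaged over the nulls where it stayed cortical. Ensembles
  are seeded and regenerate bit-identically.
* **Significance** — add-one rank p-values: (1 + #{nulls at or beyond}) /
  (1 + n), one-sided with an explicit direction.
* **Hausdorff** — max of the two directed spherical Hausdorff distances,
  in mm.
* **Variability maps** — 10-ring patches; vertices with fewer than 3
  defined patch values or a constant patch (undefined correlation) are
  NaN.

## Network discovery

Per subject, parcel mean time courses (borders/medial wall excluded) are
correlated pairwise and the top 10% of off-diagonal upper-triangle entries
(⌈0.10·n(n−1)/2⌉, ties by pair index) become unit edges; the group matrix
averages the subject binaries. Clustering is spherical k-means on
row-normalized profiles — cosine objective, 50 restarts by default, empty
clusters re-seeded with the worst-fit point, best objective kept,
deterministic under a seed. It is the documented stand-in for a mixture
model over connectivity profiles.

The Amari-type similarity of two clusterings is computed from their k×k
count confusion matrix Q: the index averages the row-wise and column-wise
mismatch terms `1 − max/sum` (rows/columns of unused labels are skipped),
and similarity = 1 − index; it is label-permutation invariant and equals 1
exactly for identical partitions. Split-half stability repeats
(split, cluster both halves, compare) 200 times per k over k ∈ [2, 30] by
default; the curve is reported and candidate peaks are never auto-selected
into a "true" k.

## Development

Node local efficiency binarizes by retained-connection fraction (same
ceiling/tie rules), takes the subgraph induced by a node's neighbors, and
averages inverse shortest-path lengths; unreachable pairs contribute 0
(1/∞) and nodes with fewer than 2 neighbors score 0. The threshold sweep
keeps 50% down to 5% of connections in 1% steps (46 points) and the
trapezoidal AUC is normalized by the 0.45 grid span, making the summary a
density in [0, 1] invariant to uniform weight rescaling.

Sliding age windows are centered at whole months 2–24 with width
`90 + 4·(m − 2)` days and closed intervals, so scans belong to every
window containing their age and consecutive windows overlap. Note the
increment rule gives 178 days at 24 months, not 182; the stated increment
is implemented and the discrepancy documented here rather than silently
resolved. Months are converted at 365.25/12 days. Windowed trajectories
are unweighted means of per-scan parcel metrics; empty windows are NaN.

## Synthetic cohort generator

The generator emulates the *structure* of a longitudinal infant rs-fMRI
cohort: an icosphere (10·4^s + 2 vertices) with a polar cap (default 5% of
vertices) as medial wall; a geodesic Voronoi ground-truth parcellation
whose seeds come from farthest-point sampling with a random start — cortical
areas are roughly evenly sized, and evenly spread basins are also what a
3-ring minimum detector can resolve at desk-scale resolution; balanced
random parcel→network assignments (equal sizes ±1, so that coarser merges
of networks are tie-degenerate and the network count is identifiable from
stability); and per-subject smooth random spherical warps (white noise
smoothed at 0.35·radius, tangent-projected, scaled to a maximum angular
displacement, default 5°) applied to the vertex→parcel assignment.

Signals are unit-variance AR(1) latents (ρ = 0.3, so correlation estimates
have realistic variance): network latents shared within a network
(coupling w = 0.6), parcel-private latents, vertex-private latents
(within-parcel coherence c = 0.95) and i.i.d. unit-variance vertex noise;
SNR (default 5) is the parcel-signal to vertex-noise standard-deviation
ratio. Default cohort: s = 3 (642 vertices), 20 parcels, 4 networks, 12
subjects spread round-robin over age groups at 3, 6, 9, 12, 18, 24 months
(±15 days jitter), one visit with one AP/PA scan pair, T = 300.

**What passing tests do and do not show.** The generator plants piecewise-
constant connectivity with known borders, isotropic noise and purely
geometric misalignment; it contains no hemodynamics, motion, physiological
noise, distance-dependent correlation structure, or gradual (non-step)
areal transitions. Recovery results therefore validate the machinery —
that the pipeline finds the borders that are there — not the biological
claim that infant cortex has such borders; all data-bound quantities
(specific parcel counts, network counts per age, reproducibility levels of
real cohorts) are out of scope.

## Problem sizes

The test battery runs the full pipeline at V = 642 (recovery, registration,
null models; 12 subjects, T = 300) and V = 162 for unit tests, with
oracle-equivalence checks at V ≤ 162 and ≤ 12-node graphs; these sizes were
chosen so the whole suite completes in a few minutes while the recovery
problems remain non-trivial (20 basins at a 3-ring seeding resolution is a
deliberately tight fit, see the smoothing note above).
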