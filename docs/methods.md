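# Methods

`fieldmorph` implements the geometry needed to compare and pool
*projected fields* — body-surface annotations of sensations evoked by
neural-interface stimulation — across different body representations: a
3D mesh versus a flat 2D illustration, or two different 3D meshes of the
same body part (a patient-specific scan versus a generic model).

## The annotation model

An annotation (`ProjectedField`) is a set of mesh faces — the face is
the paint/erase unit — plus optional hotspots (3D points of most intense
sensation on the surface), three visual-analog ratings (naturalness,
pain, overall intensity, each stored normalized to [0, 1]) and a list of
quality descriptors, each with its own intensity and a perceived depth
(above/at/below the skin).  The per-vertex binary view used by transfer
is derived deterministically: an annotated face sets all three of its
vertices; a face is recovered from a vertex array when all three of its
vertices are set.  That round trip closes a face set under "all vertices
touched" and is a fixed point thereafter.

## Landmarks and the dependency tree

Alignment is driven by named anatomical landmarks.  The canonical hand
scheme has 22 primary landmarks (5 digit tips, 8 finger DIP/PIP joints,
the thumb IP joint, 5 MCP joints, palmar and dorsal palm centers, and
the wrist base, which is the anchor) and 32 accessory width markers (a
thumb-side `_t` / pinky-side `_p` pair halfway along each of the 14
digit segments, two wrist–palm junction markers, and two palm-width
markers), 54 points in all.  Accessory names attach to a primary base
name by suffix (`Rdip_t` belongs to `Rdip`).  The naming table itself
(digit initial + joint abbreviation) is this package's convention; any
names work as long as the two sets being aligned match.

Primary landmarks are organized into a dependency tree rooted at the
anchor (wrist → MCP → PIP → DIP → tip per finger; wrist → MCP → IP → tip
for the thumb; wrist → palm centers), stored as an ordered list of
parent→child pairs in topological order.  A pair's child name doubles as
the id of the body segment it terminates.

## The morph

1. **Initial alignment.**  One unrestricted similarity Procrustes fit
   (translation, rotation, reflection permitted, scale) over all matched
   landmarks, computed by SVD of the cross-covariance (the standard
   least-squares similarity estimator), applied to mesh and landmarks;
   then a rigid translation placing the two anchors exactly together.
   Reference landmark sets from 2D illustrations carry z = 0.

2. **Vertex→segment assignment.**  Temporary landmarks are interpolated
   along each dependency segment at spacing at most `spacing` (default
   0.05 × the anchor-to-farthest-primary distance, making the density
   scale-free).  Each vertex is owned by the segment of its nearest
   temporary landmark (ties go to the earlier segment in dependency
   order — deterministic).  Segments sharing a dependency edge with the
   owner get partial influence: weight ∝ exp(−d_s / λ), where d_s is the
   distance to segment s's nearest temporary landmark and λ is the
   falloff length, default 0.25 × the owning segment's landmark-to-
   landmark length.  Weights are normalized to sum to 1 per vertex.

3. **Segmented sweep.**  For each dependency pair in order: collect the
   pair's two primary landmarks plus all accessory landmarks sharing
   their base names; fit a similarity Procrustes (scale fitted, but
   reflection excluded by flipping the smallest-singular-value axis)
   from the superset's current positions to its targets; apply the fit
   to those landmarks, and move each vertex with weight w on the pair's
   child segment to w·T(x) + (1−w)·x of its current position.  Weighted
   blending prevents tearing at joints; `blend="hard"` applies T fully
   to owned vertices instead.  Transforms compose sequentially down the
   tree, so distal segments ride along with their parents.

**Convergence.**  Because a pair's superset contains the *parent*
segment's width markers, whose target positions follow the parent's
transform rather than the child's, an articulated deformation is never
exactly representable by the per-pair fits: a single sweep leaves a
landmark residual that grows with articulation magnitude.  Sweeping
repeatedly with fixed targets contracts the residual to a fixed point.
`n_passes=1` (default) is the minimal procedure; `n_passes="auto"`
iterates until the landmark RMS improves by less than 10⁻⁶ of the
target cloud's extent (cap 64 sweeps), in the spirit of iterated
generalized Procrustes alignment.  Only the single-segment case (one
dependency pair, targets an exact similarity of the sources) is
recovered exactly in one sweep; tests verify this to 10⁻⁹.

## Aspect partition, flattening, rasterization

With the depth vector pointing from the illustration plane toward the
viewer (+z by convention; the illustration lives in z = 0), each face's
normal angle θ = arccos(n·d) classifies it: **palmar** for θ ∈ [0°, 90°),
**dorsal** for θ ∈ [90°, 180°] (the exact-90° tie goes to dorsal — a
deterministic choice the two half-open published ranges require), and
additionally **oblique** for θ strictly inside (60°, 120°), without
leaving its aspect.  The obliqueness of an annotation is the fraction of
its *annotated* surface area on oblique faces (the denominator is the
annotation's own area, not the whole mesh); it is invariant under mesh
refinement and under rotation about the depth vector, and is undefined
(an error) for empty annotations.

Flattening zeroes the depth component of every vertex and leaves
in-plane coordinates untouched (idempotent).  Rasterization marks a
pixel when its center lies inside **or on the boundary of** at least one
annotated projected triangle — pure pixel-center sampling, no partial
coverage, matching the binarized-pixel 2D maps being compared against.
The edge-function test uses exact comparisons (≥ 0), so its counts equal
an exhaustive point-in-triangle oracle bit for bit.  Occlusion is
deliberately not resolved: all same-aspect faces rasterize, so the mask
records the union silhouette, exactly as a flattened 3D annotation map
does.  The Jaccard index is |A∩B| / |A∪B| on identical grids, with the
empty∪empty case defined as 0 (no agreement claimable).

## Cross-mesh transfer

After both meshes are in a common frame, a sparse matrix T (target
vertices × source vertices) is built once per pair.  Per target face: the
k nearest source faces by centroid distance (a k-d tree over source face
centroids; "face location" means the centroid throughout); all vertices
re-zeroed about the target face centroid; rotated so the target normal
points along +z (Rodrigues construction; the antiparallel case uses a
180° rotation about x); source z components zeroed.  Each source face's
overlap with the projected target face — convex clipping
(Sutherland–Hodgman) plus the shoelace formula, with sub-10⁻¹² areas
treated as zero — divided by the target face area is its proportional
coverage, written additively into T at all 3×3 (target-vertex,
source-vertex) combinations.  Additive accumulation across faces sharing
vertices preserves the total-coverage meaning of the threshold rule.
The full coverage value is stored per entry (not split across vertices):
that convention makes the worked threshold arithmetic exact — a target
face half-covered by fully annotated source faces receives per-vertex
sums of exactly 3 × 0.5 = 1.5.

`k = max(30, ceil(30 × source_faces / target_faces))`: 30 suits a 1:1
face-count ratio and scales with source density so the neighborhood
covers comparable surface area.  Projecting an annotation computes
s = T·a over the source per-vertex array and annotates target vertices
with s ≥ 1.5 (inclusive); faces are then recovered from the vertex
array.  The threshold is exposed as a parameter.

Properties and costs of this rule, verified in tests: projection is
monotone in the source annotation; the matrix is equivariant under rigid
motions of both meshes; a plane-tiling source yields per-face total
coverage exactly 1.  Because half coverage suffices, a transferred patch
dilates by roughly one face ring at its boundary — visible for small
patches on coarse targets.  By default source faces contribute by
absolute projected area regardless of orientation (proximity is the only
filter); `require_facing=True` drops source faces whose normals oppose
the target's, which matters for thin or folded geometry where the
opposite surface sits within k-NN range.  Hotspots and quality
descriptors are not resolved through the matrix: qualities and scale
ratings copy verbatim, hotspots are dropped (they travel with the mesh
during the morph instead).

## The synthetic generator

`make_hand` builds a deterministic toy right hand: a closed genus-0 slab
over a rectilinear grid — palm block, four finger strips along +y, a
thumb strip leaving the radial side — with the full 54-landmark
complement and the canonical dependency tree.  The slab construction
(top and bottom sheets joined by a boundary band) is manifold by
construction, which a boolean union of capsule primitives would not
guarantee.  Defaults: finger segments 1.0 model units, thumb segments
1.2, finger/thumb radii 0.35/0.45, palm 4.2 × 4.0, thickness 0.9,
grid subdivision 1 (≈670 faces; every digit segment has ≥ 12 faces, so
width markers always sit on distinct geometry).

`make_2d_reference` articulates a flattened copy of the landmarks: each
segment rotates and scales in-plane about its parent joint, propagating
to descendants, so chains stay attached.  Default magnitudes — angles
uniform on ±12°, scales on [0.9, 1.1] — represent the pose and
proportion differences between a 3D model and a drawn illustration of
the same hand.  `make_patch_field` grows a connected patch by Dijkstra
distance over the face-adjacency graph with centroid-hop edge weights, a
cheap geodesic surrogate that is exact in the limits (radius 0 → the
center face; radius beyond the diameter → every face).

What the toy hand does **not** emulate: volumetric roundness (it is a
thin slab, so cross-mesh transfer without `require_facing` bleeds to the
opposite sheet far more readily than on a real hand), scan noise and
non-manifold artifacts of photogrammetry, realistic finger curvature, or
skin deformation.  Tests passing on these fixtures demonstrate the
algorithms' correctness and invariances, not robustness to real scan
pathology.

## Numerical conventions

- Vertex indexing 0-based internally; OBJ's 1-based converted at the
  boundary.  Degenerate faces (area < 10⁻¹² units²) dropped at load with
  a warning; the vertex array is never renumbered, so stored annotation
  indices stay valid.
- OBJ written at 9 significant digits (text round trips reproduce
  coordinates to printed precision; face indices exactly).  GLB stores
  float32, so round trips are exact only to single precision.  GLB files
  must contain a single mesh primitive.
- Procrustes requires ≥ 3 non-collinear points; rank-deficient
  configurations raise.  Fitted scale must be positive.
- Landmark suffix convention: base name is the text before the first
  underscore; `_t` = thumb-side, `_p` = pinky-side width marker.
- Mirroring negates one coordinate and swaps two face columns, so it is
  an involution preserving areas exactly and keeping normals outward.

## Problem sizes

The test suite and the acceptance script run on deliberately small
inputs chosen to exercise every code path at interactive speeds: the
default ~670-face hand, 288-face flat sheets, a 1,280-face sphere, a
10,000-face cylinder for the obliqueness limit, and the 3-face coplanar
pair for the threshold arithmetic.  All fixtures are generated in code;
nothing is downloaded or stored.
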