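# Methods

## The model

A planar vein network is treated as a Maxwell form diagram Γ: vertices
are vein junctions, edges are straight members, faces are the cells of
the embedding (internal faces counter-clockwise, the outer face
clockwise, Euler's relation enforced on construction).  Its reciprocal
force diagram Γ† places one vertex per internal cell and one edge per
interior member; a drawing of Γ† is *reciprocal* when every dual edge
is perpendicular to its partner.  Dual edge lengths are then member
force magnitudes, each closed dual face is the force polygon of one
internal node, and the sign of a dual edge's orientation relative to
the +90° rotation of its member encodes tension versus compression.
The engine computes a *possible* equilibrium of the projected 2-D
network; it makes no claim about the loads the living wing actually
carries.

## Perpendicularization

The drawing is found by alternating projection between two linear
subspaces of edge-vector fields: fields perpendicular edge-by-edge to
the form, and fields consistent with some vertex placement.  One
iteration rotates every dual edge vector onto its perpendicular target
and re-assembles positions by a prefactorized graph-Laplacian least
squares (one pinned vertex per connected dual component).  The
perpendicularity defect — the L2 norm of the tangential edge-field
component — is provably non-increasing across iterations; the mean
per-edge angular deviation δ (degrees from 90°) is the reported,
physically meaningful statistic but is not exactly monotone because
each edge's normalization changes as the drawing deforms.  Stopping
rule: mean δ ≤ 0.01° or 10 000 iterations.  A `direct` mode projects
the starting drawing onto the constraint nullspace in closed form
(dense least squares below ~2 000 unknowns, LSQR above) and reaches
float precision in one step.  The final diagram is scaled so the
longest dual edge has length `scale` (default 1), the family being
defined only up to scaling.

### Non-uniqueness and the canonical seed

For a fully triangulated form, the space of perpendicular drawings of
the interior dual has dimension V − 1; the converged drawing therefore
depends on the seed.  The package's canonical choice for triangulated
networks is the circumcenter (Voronoi) seed: the Voronoi diagram is
exactly perpendicular to its Delaunay triangulation, is embedded, and
is deterministic, so `dual_topology(net, seed="circumcenter")`
followed by perpendicularization reproduces the same force magnitudes
every time.  The centroid seed remains the default because it applies
to any convex-celled network.

## GDoF and static determinacy

The geometric degrees of freedom are the nullity of the dual closure
system: one scalar unknown per edge (the signed dual edge length along
its fixed perpendicular direction) and, for every internal face, the
closure of the duals of its boundary edges (equivalently, rotating the
equation by 90°, the weighted closure of the face's own edge
vectors).  For any edge-connected triangulation the per-face solutions
chain into a single global scale, so the nullity is exactly 1 and the
force diagram is unique up to scale — static determinacy.  A lone
triangle likewise gives 1 (one closed polygon, free scale); two quads
sharing an edge give ≥ 2.  Rank is counted by SVD with singular values
below 1e−8 of the largest treated as zero; an exact-rational
elimination oracle checks the numeric rank on all small fixtures.

## Form reconstruction

Given a converged force diagram, target lengths per member and at
least two anchor vertices, form coordinates solve a sparse least
squares with two rows per member written in the (tangent, normal)
frame of the member's required direction: tangential component equals
the target length, normal component equals zero.  With consistent
targets (the original lengths) the round trip reproduces the geometry
to ~1e−15 of the bounding-box diagonal.  An optional
`direction_weight` up-weights the normal rows so that *inconsistent*
targets — learned predictions — are projected onto the consistent
reciprocal family instead of folding the drawing, and an optional
proximity (Tikhonov) term pulls free vertices toward a reference
drawing, providing a trust region around a known-planar solution.

## Member sizing, accuracy, boundary completion

Diameters are strictly proportional to dual edge lengths, `d = k·F`
with `k = d_max / F_max`; zero-force members (possible after T→Y
repair, or from cocircular triangle pairs whose dual edges vanish) are
floored at `d_min = d_max/20` for export only and flagged.  Thickness
agreement is scored per edge on normalized radii, `θ = 1 − |R_real −
R_generated|`; the unweighted mean is reported and, when form edge
lengths are supplied, the length-weighted mean as well, since the
aggregation underlying a single percentage is otherwise ambiguous.
Boundary members are assigned forces proportional to their measured
widths with the same `k`; the virtual load at each peripheral vertex
is minus the vector sum of its incident member forces, which closes
every boundary force polygon and satisfies global force and moment
equilibrium identically.  The unified diagram is the Minkowski
combination `x_v + scale·x†_f` over incident (vertex, face) pairs:
cells translate rigidly, members become parallelograms of width
proportional to their force, internal nodes grow into their scaled
force polygons, and for a valid scale the three families tile the
combined region with no overlap (validated by comparing the polygon
area sum with the union area).

## Main-path raster codec

The force main path is an RGB raster: R ∈ {0, 255} marks region
membership, B ∈ {0, 255} marks force-edge midpoints, G linearly
quantizes the force-edge length between the `L_min`/`L_max` recorded
in a sidecar JSON (`G = round(255·(L − L_min)/(L_max − L_min))`
clipped to [0, 255]), and all-zero pixels adjacent to a region are its
boundary curve.  Since the plain background is also all-zero, the
decoder identifies boundary pixels by adjacency to a region — the
reading that keeps the channel semantics self-consistent.  Encoding
fails loudly when two midpoints would land on the same or adjacent
pixels (information would be silently lost); the wing encoder retries
at a larger canvas instead.  Decoding thresholds R and B at 128 and
supports a morphological opening for ragged learned output; encode →
decode recovers midpoints within 1 px and lengths within one
quantization step.

Force-geometry reconstruction simplifies the region boundary at 1.5 px
(Douglas–Peucker), takes decoded midpoints as interior sites (skeleton
junctions only stand in when a raster carries no midpoint data, since
band skeletons are ragged), densifies the outline to the interior site
spacing with a half-pixel inward offset (exactly collinear points
degenerate the triangulation), and Delaunay-triangulates; every face
is convex by construction and the result satisfies the dual-topology
preconditions or raises.

## Wing vectorization

Binarize (Otsu by default) → skeletonize → junction/endpoint
classification → path tracing with corner splitting (closed outlines
have no junctions, so cycles are split at curvature corners) → a
cleanup cascade in units of the measured local stroke width: junction
blob contraction, collinear degree-2 straightening, least-squares
line-fit refinement of every vertex from its incident edges' reliable
mid-pixels, and crossing repair.  Widths are twice the median
Euclidean distance transform along the middle of each traced
centerline, which is robust to junction blobs.  On well-conditioned
fixtures (minimum junction angle ≈ 30°) the render → vectorize round
trip recovers V, E, F exactly at stroke widths 3–15 px with widths
within ±1 px for ≥ 95% of edges.  Known limitation: junctions meeting
at very shallow angles (the long narrow leading-edge band cells meet
the leading edge at ~7°) merge over a distance `~w/sin(θ/2)` that
scales with the stroke width, so no skeleton-based tracer can recover
such vertices exactly at realistic widths; wing renderings still
recover the cell count exactly.

## Learned stages

The edge-length regressor is a scikit-learn estimator: a (64, 64) tanh
network on standardized features trained with deterministic L-BFGS
(fixed seed ⇒ identical weights), features normalized to the force
diagram's bounding box and maximum force, targets to the form's
bounding-box diagonal.  It recovers a planted inverse-force length
rule with validation R² ≥ 0.99 at n = 2 000 (≥ 0.98 under 2%
multiplicative noise).  The boundary→main-path translator is a
reduced-resolution (default 32²) fully connected encoder–decoder;
inputs are inverted so strokes are the positive signal, sparse target
channels are dilated before downscaling (the decoder re-centroids
blobs), and outputs are post-processed with response-relative
thresholds to restore the hard channel invariants.  A deterministic
fallback — inward-offset leading-edge band, two staggered rows of
seeded midpoints, front-to-back declining lengths — guarantees a
decodable raster for any closed boundary; the learned path falls back
with a warning if its output does not decode.  Rotation augmentation
turns 21 pairs into 147 via the seven angles −15°…15°, padding when
content would clip.

### End-to-end regeneration

boundary → main path → decode → triangulated force geometry → swap
(force faces become form vertices) → predicted lengths →
least-squares form.  The swap derives each member's tension /
compression sense from the exact circumcenter-seeded drawing (obtuse
triangle pairs flip it), merges cocircular triangle pairs whose dual
edges vanish into convex quads, and then solves with hard
perpendicularity plus a proximity homotopy toward the seed drawing
scaled by the predicted global size, relaxed only as far as the planar
embedding survives.  With weakly informative regressors (wing-corpus
training yields low R², near-constant predictions) the guard
dominates and the learned stage effectively sets the global scale;
with informative models lower proximity weights win.  Fallback-mode
regeneration therefore always yields a valid convex-celled network,
whose own reciprocal analysis converges far below the deviation of a
digitized wing.

## Synthetic wings

The generator emulates the structural signature the analysis relies
on, not wing development: a convex elongated outline (chord 4, depth
1, blunt caps), a row of wide shallow cells along the leading edge
(the analogue of the long narrow cells between the longitudinal
veins) whose depth profile is shallowest at mid-chord, and a jittered
hex-lattice secondary mesh below.  Point counts are adjusted until the
internal face count matches the request exactly (interior points
change it by two, outline points by one).  The reciprocal is computed
at machine tolerance from the circumcenter seed; widths are planted as
`d = k·F` with `d_max = 60 px` (boundary members taper from 0.9·d_max
at the leading edge to 0.35·d_max), and noise, when requested, is
multiplicative log-normal, widths being positive and heteroskedastic
in images.  The seeded jitter draw is re-derived deterministically
until the wing satisfies its primary-path postcondition — top-decile
force members connected across ≥ 60% of the chord — so equal specs
give byte-identical output.  Emergent properties: GDoF is exactly 1
for every seed and size tested (10 seeds × 20/50/200 cells);
circularity is bounded above by the equilateral-triangle value
π√3/9 ≈ 0.605, with the bulk of cells in [0.5, 0.6] and the primary
band cells in the low tail.  What passing tests on these wings do
*not* show: robustness to photographic artifacts (shadows, lens
distortion, broken veins), non-triangular cell mosaics, or the
morphometric distributions of real species.

## Problem sizes and numerical choices

Default test and acceptance runs use wings of 20–220 cells, rasters of
384×128 to ~1000×400 px, a 10-wing corpus for pipeline checks and 25
wings for the split bookkeeping, chosen to keep the full suite in the
low minutes on one CPU while exercising every code path at realistic
density.  Vertex merge tolerance is 1e−6 of the bounding-box diagonal;
GDoF rank tolerance 1e−8 of the largest singular value; convexity
demands strictly positive turns (degree-2 vertices can never satisfy
it in both incident faces, which is the zero-force T-joint situation
that the T→Y repair exists to remove); boundary-polyline
simplification is 1.5 px.  All randomness flows through
`numpy.random.default_rng` seeds carried in specs and configs.
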