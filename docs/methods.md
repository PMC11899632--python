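# Methods

This note documents the models, numerical choices and limitations behind
`psiplate`, in the order the pipeline runs them.

## Trace curves

Both the sweep path (C1) and the guide curve (C2) are parameterized on the
integer index scale ns = 1..n of the picked points, not on chord length:
the smoothing objective is defined against that scale, and keeping it makes
the smoothing parameter P directly comparable across plans. Interpolation
is a natural cubic spline (`scipy.interpolate.CubicSpline`,
`bc_type="natural"`) evaluated at n + (n−1)·q uniform parameter values;
q defaults to 10 inserted points per segment.

Smoothing minimises `P·Σ wᵢ|xᵢ−S(nsᵢ)|² + (1−P)·∫S″²` per coordinate with
w ≡ 1 and λ ≡ 1. Dividing by P shows this is the classical penalized
smoothing spline with λ_scipy = (1−P)/P, so mid-range P is delegated to
`scipy.interpolate.make_smoothing_spline`. The limits are special-cased:
P = 1 returns the data (the residual term dominates), P = 0 returns the
weighted least-squares line (the curvature term forces S″ = 0). For n < 5
(below scipy's minimum) the knot values are obtained from the
Green–Silverman normal equations `(W + λ·Q R⁻¹ Qᵀ) g = W y` directly.
The default P = 0.99 keeps the plate within a few tenths of a millimetre
of the picks while removing the corner spikes that would otherwise
concentrate stress; it is a tunable "allowable error" knob.

After smoothing, the path is resampled uniformly by chord length at a
0.5 mm default pitch so sweep sections are evenly spaced; the guide is
resampled to the same count and reversed if that lowers the summed
index-wise distance to the path. Only whole-curve reversal is considered —
per-point permutations could introduce crossings and are excluded by
design.

## Sweep

Frames use the backward-difference tangent v̂ₙ (first frame copies the
second, where the backward difference is undefined) and the angulation
vector ûₙ from path to guide; a sign flag flips ûₙ for plans whose guide
lies on the other side. The rectangle is placed by the staged construction
z-rotation → axis-angle rotation about the updated in-plane axis →
translation → roll, with the printed-form z-rotation angle chosen so the
rectangle's normal actually lands on v̂ₙ, and the axis-angle step using the
standard Rodrigues matrix (an orthogonal rotation; the staged construction
is otherwise followed as described). The roll angle is made unique by the
convention γₙ = atan2((w×û)·v̂, w·û), where w points along the current
long axis: rolling by γₙ aligns the long side with the projection of ûₙ
into the section plane, which maximises its overlap with ûₙ. Corner order
is g1 = (+t/2, +ℍ), g2 = (+t/2, −ℍ), g3 = (−t/2, −ℍ), g4 = (−t/2, +ℍ)
(a CCW loop about the section normal), so ½(g1+g4) − c is the long-axis
direction used for w.

Hole-adaptive heights: interior sections use max(ℍ, Ḣ) — the boss only
ever widens the plate — while end-zone sections (outside the two end
holes) use Ḣ = √((D/2)² − k²) exactly, terminating the plate in discs of
diameter D. End holes sit at arc length D/2 inside each terminus. Tip
sections whose half-height falls below 0.05 mm are trimmed so the end caps
never degenerate to zero-area rectangles; the trimmed sliver is a
sub-0.05 mm cap of the disc.

## Overlap pruning

The separating-axis test uses the two face normals, the 16 edge-direction
cross products, and additionally the in-plane edge normals n×e of both
rectangles — without the latter, coplanar overlapping rectangles would be
classified disjoint (every cross product of in-plane edges is parallel to
the shared normal and carries no information). Diagonal corner differences
add only redundant axes and are omitted. Tolerance semantics: an axis with
a genuine gap (> 1e-9 mm) separates; grazing contact separates only on
axes where both rectangles have real extent, because each rectangle
projects to a single point on its own normal axis and that degenerate
"zero overlap" must not discard genuine transversal crossings.

Pruning removes the rectangle with the highest intersection degree,
breaking ties toward the lowest index, until no intersections remain;
removing a rectangle never creates intersections, so the graph is built
once. Path-adjacent pairs (|i−j| ≤ 1) are exempt — they touch by
construction and skinning relies on them.

## Skinning

Corner j of section n joins corner j of section n+1; each side-wall quad is
split along its shorter diagonal (avoids slivers on twisted segments), and
the two end sections are capped. The CCW corner loops fix a consistent
outward orientation. A flipped correspondence (bowtie wall quad) raises an
error naming the segment rather than producing a folded surface; the roll
continuity of the sweep prevents this on smooth paths.

## Holes

All holes share one countersink geometry: shaft diameter φ = 2.0 mm, head
Ø = 3.5 mm, half-angle ß = 45°, 64 circle segments, height = plate
thickness + 0.2 mm overshoot per side so every cut is a guaranteed
through-cut. ß is interpreted as the countersink half-angle from the hole
axis, which fixes the head height ħ = ((Ø−φ)/2)/tan ß; if an inconsistent
ħ is supplied the angle wins and a warning reports the implied value. The
hole axis is the local plate-thickness direction v̂ × ŵ (the "hole vector"
is named in the workflow description but never computed there; the
thickness normal is the only direction that makes a through-cut). The
cutting solid is a surface of revolution built from stacked circles with
triangulated walls and fan caps; its volume converges to the analytic
solid of revolution as segments⁻².

## Boolean subtraction

No manifold-Boolean kernel is assumed: the subtraction is implemented in
the package as surface co-refinement plus winding-number classification.
Per intersecting triangle pair a transversal intersection segment is
computed by clipping the plane–plane line to both triangles; endpoints cut
by a given edge/plane combination are produced by identical arithmetic in
both meshes and are additionally welded globally (1e-9 mm) so both
surfaces see bitwise-identical intersection polylines. Each affected
triangle is retriangulated in its own plane with shapely: merged constraint
chains are extended 1e-6 mm past the triangle boundary and used to split
the triangle polygon; closed loops are handled by polygon difference; faces
with interior rings are bridged to their shell and ear-clipped. Facets are
then classified by generalized winding number (van Oosterom solid-angle
sum) at their centroids: plate facets outside the hole and hole facets
inside the plate (orientation reversed) are kept. Two cleanups make the
stitched surface exactly watertight: zero-area ear slivers from collinear
chain vertices are dropped, and a T-junction pass splits any edge passing
through another vertex. The output must pass the watertight + oriented
diagnostics or the operation raises.

Limitations: coplanar (tangential) surface contact is not treated as an
intersection — hole placement guarantees transversal cuts via the
overshoot — and near-tangential crossings with contact angles below ~1e-5
rad could defeat the 1e-9 mm weld. Holes are validated pairwise disjoint
before subtracting, so the sequential order cannot matter.

## Mesh I/O and diagnostics

STL (ASCII and binary, 80-byte header + 50 bytes/facet) is read and
written directly; stored facet normals are ignored on read and recomputed
from CCW winding on write, making "normals point outward" a computed
property instead of trusted input. Duplicate vertices are welded at
1e-6 mm (union-find over KD-tree pairs) — STL duplicates every shared
vertex, and welding is what makes edge-based topology meaningful.
Watertightness is "every undirected edge borders exactly two faces",
orientation is "no directed edge is traversed twice", and genus comes from
χ = V − E + F = 2 − 2g (meaningful only for closed oriented surfaces).
Triangle statistics are reported as edge lengths; "triangle size" in
informal usage is ambiguous between edge length and area, so the
unambiguous quantity is exposed.

## Statics

The nine unknowns (T, CL, CR components) solve a 9×9 system: three force
rows, three moment rows about the origin (any reference point gives the
same solution for a balanced system — verified by a common-translation
test), and three angle rows in the form sin θ·den − cos θ·num = 0. The tan
forms are singular at 90°, which is the customary γ, hence the sine/cosine
form. The moment balance as printed repeats the y-row; the implemented
sixth equation is ΣM_z = 0, without which the system is rank deficient.
Rank deficiency (e.g. degenerate angle/geometry combinations) raises an
error reporting the SVD null direction. Angles are degrees in I/O, radians
internally.

The packaged muscle table carries the twelve published right-molar
clenching force vectors; its attachment coordinates are synthetic
(plausible mandible geometry authored here — no measured coordinates are
published), so solved reaction magnitudes are geometry-dependent
illustrations, not reference values. The bite-force scaling
s = bite / |T| is implemented exactly as defined; note that the published
scaled table is numerically closer to a rounded s = 0.25 than to
91/365.13 = 0.2492 for most entries — the package follows the formula, and
only scale-insensitive entries are used as checks.

## Synthetic data

`make_bone` generates a watertight tube along a circular arc (default
80 mm long, 60 mm bend radius, 6 mm cross-radius, 60×32 grid) with seeded
radial jitter of 0.08 mm emulating surface roughness; `make_plan` lays the
picks on the analytic outer surface (C2 offset 35° poloidally) and jitters
hole picks by 0.2 mm to exercise snapping. This emulates the geometry of
the task — a curved bone with picks on it — but none of the anatomy:
no resection gaps, no fibula segment boundaries, no real mandible
curvature profile. Passing tests therefore certify the geometric engine
and its invariants, not clinical fitness of any particular plate.
`make_statics_case` forward-constructs equilibrium problems: it plants
reactions satisfying the angle constraints and synthesizes muscles whose
wrench balances them (a point force for the perpendicular moment component
plus a force couple for the parallel remainder), giving recovery oracles
that are exact by construction.

## Problem sizes and determinism

Defaults produce ~150 sections and ~5k output triangles per plate; tests
run the same geometry at 0.8–0.9 mm pitch and 24–32 hole segments, which
exercises every code path at a few seconds per plate. There is no
randomness anywhere in the design path — identical inputs give
byte-identical STL output — and every synthetic generator takes an
explicit seed.
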