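# Methods

This note records the geometric model, the numerical choices behind it,
and what the synthetic fixtures do and do not demonstrate.

## Exact solids and the three basic functions

Every solid — primitive or CSG node — implements point containment,
segment intersection (as closed parameter intervals) and starting-cube
seeding. The single global boundary rule is **surface = inside**:
containment comparisons use an absolute tolerance of 1e-12 Å and
`≤` at the boundary, applied identically in every primitive. A
consequence accepted deliberately for differences: a point on the
boundary of the subtrahend `B` counts as inside `B` and is therefore
excluded from `A − B`; interval subtraction removes `B`'s closed
intervals including endpoints and re-closes the result at machine
epsilon.

Tangencies (a segment grazing a sphere, torus, edge or corner) generate
two artificial intersection points separated by `ε_tangent = 1e-9 Å`
to keep interval topology consistent. The same constant is the
interval-set merge tolerance, so tangency slivers can never produce
spurious zero-width exterior gaps.

### Spindles and the torus quartic

A spindle (the solvent-excluded neck between two atoms) is a capped
cylinder minus a coaxial torus, parametrized by center, axis, major
radius `R` (probe-center circle), minor radius `r` (probe radius) and
signed end-cap offsets at the probe-atom tangency circles. Segment
intersection transforms the segment into the canonical frame (center at
origin, axis along x) using a deterministic orthonormal completion
pivoted on the largest axis component, so results are bit-reproducible.
Substituting the parametrized line into the torus implicit gives a
monic quartic whose roots are read off as eigenvalues of the Frobenius
companion matrix; eigenvalues are accepted as real when
`|Im λ| ≤ 1e-8 · max(1, |Re λ|)`, because eigensolvers perturb real
roots into conjugate pairs near tangency. Roots are filtered to the
cylinder and cap range, combined with cap-plane crossings, and
assembled into intervals by classifying the midpoint of every gap with
the spindle's own containment test — so intervals are consistent with
containment by construction. When `R < r` the spindle is *broken* (the
probe dips past the centerline); the axis is then genuinely outside the
solid and starting-cube walks launch from both end caps toward the
center.

## Marching cubes as parallel floodfill

The output lattice snaps its origin to integer multiples of the
resolution and covers all operand boxes with one cube of padding
(hard cap 2×10⁸ cubes, configurable; exceeding it raises an error
suggesting a coarser resolution). Surface discovery is a
level-synchronous breadth-first floodfill over face-adjacent (6-neighbor)
cubes: the whole frontier is classified, survivors emit unexamined
neighbors, and the frontier swaps. Corner classifications are cached so
each distinct corner is evaluated exactly once per solid; the `workers`
argument only splits classification batches across threads and cannot
change any result.

Seeding is per input solid (cheap closed-form walks), and the union of
all per-solid surface cubes is filtered by the root solid's
mixed-corner test. Two robustness layers sit on top:

* the filtered set seeds one further floodfill over the *root* surface,
  because a thin leaf's surface cubes can be face-disconnected on the
  lattice while the output surface is connected;
* if a solid's seeds find nothing but its box overlaps the lattice, a
  bounding-box corner scan takes over (with a logged warning). Thin
  solids can occupy a cube without straddling any of its corners; a
  feature smaller than one cube everywhere still cannot be recovered —
  this is the inherent resolution limit of the lattice, and the remedy
  is a finer resolution.

### Triangulation table

The 256-case table is generated at import time rather than transcribed.
For each corner-state mask, contour segments are built per cube face;
the ambiguous face (two diagonally-inside corners) is resolved by a
fixed rule — inside corners are never connected through the face. Since
the rule depends only on the shared face's corner states, adjacent
cubes always agree, making every output mesh watertight including at
saddle configurations. Segments chain into closed loops (each crossed
cube edge lies on exactly two faces), loops are fan-triangulated, and
orientation is fixed by comparing the loop's Newell normal against the
summed inside-to-outside directions of its crossed edges, giving
outward normals everywhere. A different (equally valid) ambiguity
policy would triangulate saddle neighborhoods differently; enclosed
volumes agree to within the resolution-scale discretization error.

One intersection point is placed per mixed lattice edge, shared by all
incident cubes, taken from the root's interval boundaries as the
crossing nearest the inside corner (this guarantees consistency with
corner states when sub-resolution detail produces several crossings).
If the reported boundaries are numerically inconsistent with the corner
states, the edge falls back to 60 bisection steps on containment; the
count is logged.

## Molecular solids

The power diagram's dual (regular triangulation) is computed by lifting
the weighted atom centers to 4-d, `(x, |x|² − w)`, and taking the lower
convex hull; weights are `w = (r_vdw + r_solvent)²` so that power
vertices coincide exactly with solvent-tangent probe positions. Sets of
fewer than five atoms are handled combinatorially; degenerate
(coplanar) configurations fall back to joggled hulls. Coplanar
four-atom sets keep the complete edge/triangle graph — spindle creation
is still gated by probe geometry, so the only effect is a conservative
(slightly overfull) neck set in a measure-zero configuration class.

Per dual edge shorter than `r_a + r_b + 2 r_solvent` (the *overlong*
threshold) a spindle is created when the solvent-center circle exists;
per dual tetrahedron without an overlong edge, a tetrahedron primitive.
Triangles not buried between two solid tetrahedra are probed: tangent
probe centers come from closed-form trilateration on the expanded
spheres (zero, one or two mirror solutions), each candidate is rejected
if any fourth atom intrudes (`|c − c_j| < r_j + r_solvent − 1e-9`,
checked over a KD-tree neighborhood of radius `max r_vdw + 2 r_solvent`),
and each survivor forms a cup: a probe-sized negsphere plus the
tetrahedron spanning the triangle atoms and the probe center. Both
mirror candidates can survive on thin structures; each then contributes
its own cup. Containment applies negsphere dominance: inside any
negsphere means outside the solid, regardless of other primitives.

All primitives register in a 2 Å spatial-hash lattice by bounding box;
point and segment queries touch only hash-local primitives, and the
hash-accelerated path is verified against exhaustive evaluation in the
tests. Default van der Waals radii: H 1.20, C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80, default 1.70 Å (element-keyed, overridable); default
probe radius 1.4 Å.

Starting cubes come from negsphere-atom tangency points, spindle axis
walks, sampled points on spindle cap-tangency circles, and the spheres
of atoms untouched by any spindle — all filtered by the molecular
solid's own mixed-corner test, with the bounding-box scan as the final
fallback.

## Meshes as solids

A closed mesh (validated: every edge on exactly two triangles;
zero-area triangles dropped with a warning) is classified on an
internal lattice at a preparation resolution that defaults to the
downstream meshing resolution. Triangle-cube registration uses the
conservative bounding-box overlap, so parity queries can only see a
superset of relevant triangles. Empty-cube components (6-connected) are
labelled by segment parity: components touching the lattice border are
exterior by definition; every other component casts one segment from a
representative cube center to a point outside the lattice and counts
triangle crossings — odd means interior. This is exactly the
checking-segment rule and it also settles the thin-wall abnormality
where a void boundary and the outer surface share one cube; no separate
alternation pass is needed.

Point containment in triangle-bearing cubes is decided by majority vote
over five segments cast to nearby empty cubes (expanding rings,
distinct octants preferred). The caster is a deterministic generator
seeded from the hashed query coordinates: votes are random in the
spirit of the method but reproducible across runs and worker counts.
Any intersection suspiciously close to a triangle edge/vertex or a
segment endpoint triggers a jittered re-cast (1e-7 Å) so parity counts
never depend on razor-edge hits; the same policy guards segment
intersection, which walks hash cubes along the segment, sorts the
crossings and alternates state from the first endpoint's containment.

Isopotential extraction runs the same 256-case table directly on the
scalar grid (inside is `φ ≥ k` for positive k, `φ ≤ k` for negative),
with one layer of outside padding so open isosurfaces are capped at the
grid box and the mesh stays closed.

## Cavities, fragments, metrics

The cavity recipe is `(ligand-sphere union − small-probe solid) ∩
large-probe envelope` with defaults 5.0 / 1.4 / 5.0 Å. The envelope is
used exactly as the large-probe molecular solid, with no further
post-processing. Fragments are connected components of the triangle
adjacency graph; shells with negative signed volume are nested voids,
assigned to the smallest enclosing positive shell, so fragment volumes
sum to the Surveyor volume of the whole mesh identically. Fragment
identity across resolutions, where needed, is matched by centroid
proximity.

Displacement distance computes, for every vertex of mesh A, the exact
point-to-triangle distance to mesh B, shortlisted by a KD-tree over
triangle centroids with a provably sufficient search radius (nearest-
vertex distance plus the largest triangle half-diameter), so the
reported minimum/mean/maximum are exact, not sampled. The measure is
directional by definition.

## Synthetic fixtures and their limits

The generators emulate the study conditions at desk scale: collections
of ~30 random primitives (spheres, tetrahedra and valid probe-derived
spindles with radii 0.5–3 Å in a 20 Å box) for CSG stress and
parallel-invariance runs; toy molecules of 2–50 atoms (dimer, 4-atom
cluster, a 17-atom two-ring pocket with an optional blocker atom and a
single ligand atom, helix-like chains) shaped so each construction
stage — spindles, tetrahedra, cups, cavity steric variation — is
exercised with known combinatorics; and unscreened Coulomb grids
(`φ = Σ q_i / |x − c_i|`) standing in for Poisson-Boltzmann output,
since the mesh-solid machinery is agnostic to the field's physics.
Passing on these fixtures demonstrates geometric and algorithmic
correctness; it does not probe protein-scale primitive counts,
crystallographic pathologies (altlocs beyond the tested policy, exotic
elements), or screened electrostatics. Test problem sizes (resolutions
of 0.125–0.5 Å on solids a few tens of Å across) were chosen so the
full suite stays comfortably within a desktop run.

## Known limitations

* Features thinner than one lattice cube everywhere cannot appear in
  the output mesh (inherent to the lattice; reduce the resolution).
* Mesh-solid containment within half a triangle size of the surface is
  decided by the faceted mesh, not the smooth surface it approximates.
* The regular triangulation uses expanded-radius power weights; a tool
  using bare vdW weights could differ in near-degenerate dual
  topologies.
* Worker parallelism is thread-based over numpy batches; it guarantees
  determinism but yields modest speedups for Python-bound stages.
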