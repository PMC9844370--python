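# Methods

## Solids and their combinatorics

The five Platonic solids are built from their classical coordinate
constructions, faces recovered by merging coplanar facets of the convex
hull, and every edge normalized to length exactly 1 (tolerance 1e−9).
Unit edges make the geometric descriptors — radius of gyration,
convex-hull area and perimeter — comparable between solids and between
studies; all downstream geometry inherits this normalization.  Face
cycles are stored counterclockwise as seen from outside, so each edge is
traversed once in each direction; this consistent orientation is what
lets unfolding use rotations only (no reflections) and gives every
vertex a well-defined rotation system.

Symmetry groups are computed *combinatorially*, as the vertex bijections
preserving adjacency and the face set, so floating-point coordinates
never enter group structure.  For the Platonic solids this reproduces
the geometric groups (orders 24, 48, 48, 120, 120 with reflections;
rotation subgroups of half the order, identified by whether a face cycle
maps to a rotation or a reversal).  An asymmetric user mesh yields the
trivial group with a warning rather than an error.

## Enumerating nets

The skeleton tree (spanning tree of the face-adjacency graph, i.e. the
fold hinges) is the enumeration object, because all topological
descriptors live on it; the cutting tree is derived by complement
duality (a solid edge is cut iff its hinge is absent).  Spanning trees
are represented as bitmasks over a fixed edge ordering.  For graphs of
Platonic size (30 edges) every C(E, F−1) edge subset is visited with
Gosper's combination iterator and tested with a union-find; the kernel
is numba-compiled with a pure-Python fallback, and the streamed count is
cross-checked against the exact Kirchhoff determinant (sympy integer
arithmetic) for every solid.  The same determinant routine serves
arbitrary meshes — e.g. a 60-face T=1 capsid polyhedron, whose count
(~10³⁰) is far beyond enumeration.

Distinct nets are symmetry-orbit representatives.  Equivalence uses the
**full** group (rotations + reflections): that is the convention under
which the counts 2 / 11 / 11 / 43,380 / 43,380 are reproduced, and it was
validated against those counts rather than assumed.  Canonicalization
takes the minimum of the permuted bitmask over the group; since tree
masks fit in 2³⁰, the group action is a single float64 matrix product
per batch (sums of distinct powers of two below 2⁵³ are exact), and
orbit sizes are required to sum back to the raw tree count.
Deduplication is deliberately *not* keyed on the boundary degree
circuit: its uniqueness is a claim to measure (see below).  `net_census`
optionally persists its result to an .npz cache, making interrupted
large runs resumable; at roughly 20 s per large solid on one CPU this is
a convenience, not a necessity.

## Unfolding

Each face gets a local 2D frame (complex plane, centroid at origin,
counterclockwise).  For every hinge, the rigid motion z → αz + β mapping
one face's frame into its neighbor's is precomputed once per solid;
unfolding a given skeleton tree is then a tree traversal composing
motions from the root face (lowest face index; net posed with the root
centroid at the origin and its first edge along +x).  Hinge endpoints
are verified to coincide within 1e−9 after placement; a violation raises
with the offending face pair.  Net vertices are identified by union-find
over (face, solid-vertex) incidences merged across hinges, and the
boundary is traversed by following each face's unfolded edge slots in
orientation order — combinatorially identical to the Euler tour of the
doubled cutting tree, and equally valid for partial nets and synthetic
fixtures.

The overlap test shrinks every face toward its centroid by a fraction
1e−7 and queries pairwise interior intersection through shapely's
STRtree, so faces meeting in shared edges or vertices never register as
overlap.  An exact-arithmetic audit mode was considered and dropped: the
solids' coordinates are irrational (golden ratio), so rational
arithmetic does not apply, and symbolic intersection is impractically
slow at 43,380 nets.  The 1e−7 shrink sits about five orders of
magnitude above accumulated placement error (≲1e−12) and five below any
genuine overlap of unit faces, so the classification is robust to the
choice.

## Descriptors

*Vertex connections* (restrictive) are counted per boundary vertex as
net degree equal to m+1, where m is the number of faces at that solid
vertex — equivalent to "incident to every face it will touch on the
solid", and per-vertex m handles mixed-face meshes.  They are exactly
the leaves of the cutting tree.  The *traditional* definition counts
boundary vertices of net degree ≥ 4 (two faces sharing the vertex but
no edge), and always dominates the restrictive count.  *Leaves* are
skeleton nodes of degree 1 and always equal the A-entry of the degree
distribution.  Degree distributions are padded with zeros up to the
solid's maximal face adjacency so they are comparable across solids;
admissible distributions are all nonnegative integer solutions of
Σn_d = F and Σd·n_d = 2(F−1), of which only some are realized by actual
spanning trees (2, 4, 3, 21, 9 realized for the five solids — e.g. the
cube's four admissible solutions are all realized, by 4, 5, 1 and 1 of
its 11 nets, while the octahedron's (5,0,3) solution is not realizable).
The *backbone* length is the tree diameter from a double BFS.

The default radius of gyration is the **centroid-sum** form — the root
mean squared distance of the N face centroids from their mean — which is
the form used for the study data; the exact per-unit-area second moment
of the net region (area-integral form) is available as an alternative
and agrees on closed forms (a unit square gives Rg² = 1/6; two hinged
unit triangles give centroid-sum Rg² = 1/12).  Both are rigid-motion
invariant and scale linearly under uniform scaling.  Hull metrics come
from scipy's Qhull (in 2D, `volume` is the area and `area` the
perimeter); degenerate collinear input is rejected.

## Correlations and sampling

R² is the squared Pearson correlation, equal to the OLS coefficient of
determination in either orientation (symmetry asserted to 1e−12).  Over
all 43,380 unit-edge dodecahedron nets, hull perimeter vs centroid-sum
Rg gives R² = 0.7378 and hull area vs Rg gives R² = 0.1415, matching the
published 0.738 and 0.142 within ±0.01 — this match is what resolved
which convention (Rg, not Rg²) the published scatterplots used; the Rg²
variants give 0.7373 and 0.1392.  The association also holds inside
every vertex-connection stratum 2..10 separately (all p < 0.01).  The
stratified sampler groups nets by a stratum key (default: vertex
connections), orders each stratum by a spread key (default: hull
perimeter; ties broken by a seed-fixed shuffle) and takes k evenly
spaced order statistics — k = 3 yields minimum / closest-to-median /
maximum, and over the dodecahedron's nine strata yields 27 candidate
nets.

## Measured, not assumed

The boundary degree circuit was checked as an identifier by full
enumeration: its canonical cyclic form (minimal rotation over both
directions) is distinct for each of the 43,380 dodecahedron nets and
each of the 43,380 icosahedron nets.  Within this package's scope the
circuit is therefore a perfect net identifier, but orbit keys remain the
deduplication mechanism since the property is empirical, not proven.

## Synthetic fixtures and their limits

`make_fixture` builds adversarial pseudo-nets: a fan of n ≥ 7 unit
triangles around one vertex (angular excess forces interior overlap — a
guaranteed violation of the non-overlap property), a chain of n squares
(path skeleton: 2 leaves, diameter n−1) and a k-gon star (k leaves,
diameter 2).  These exercise the negative paths of the overlap test and
the skeleton metrics.  They are flat constructions, not unfoldings of
any solid, so they carry no cutting tree and no vertex-connection
semantics — passing tests on them validates the net machinery, not any
claim about real polyhedra, which is what the exhaustive Platonic
enumeration is for.

## Problem sizes and determinism

The package enumerates both large solids exhaustively (5,184,000 trees
each) rather than sampling; a census takes ~20 s and the full
43,380-row dodecahedron descriptor table ~30 s on one CPU.  Full-sweep
validations (overlap-freeness and boundary length of every net of both
large solids) are part of the test suite.  All outputs are deterministic
given the configuration: enumeration order follows canonical bitmasks,
CSV/JSON orderings are fixed, coordinates serialize with 12 significant
digits, and the only stochastic step (tie-breaking in stratified
sampling) is governed by an explicit seed (default 0).

## Known limitations

Only convex polyhedra are supported (edge unfoldings of non-convex
solids need not exist); bitmask enumeration requires < 62 graph edges
and a C(E, F−1) search space below ~2×10⁸, beyond which only the
matrix-tree count is offered; the overlap test is floating-point with
the shrink heuristic described above; and foldability here is purely
static — no kinetics, energies or fold-order simulation.
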