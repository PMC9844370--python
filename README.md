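# durernet

Exhaustive enumeration of the **Dürer nets** (edge unfoldings) of the
Platonic solids and computation of the topological and geometric
descriptors that predict how well a net self-folds into a closed
polyhedron — the planar-to-3D problem underlying models of icosahedral
viral-capsid assembly, self-folding origami, and 4D-printing design.

## Who this is for

Researchers designing self-folding experiments (which of the tens of
thousands of unfoldings of an icosahedron should you print?), students of
polyhedral combinatorics, and anyone modelling a T=1 capsid as 20
triangular capsomeres that must find their way from a flat sheet to a
closed shell.

## The model

A *Dürer net* of a convex polyhedron is planar, a single piece, produced
by cutting edges only, and non-self-overlapping.  Cutting along a
spanning tree of the solid's vertices (the **cutting tree**, V−1 edges)
flattens the surface; dually, the faces left hinged together form a
spanning tree of the face-adjacency graph (the **skeleton tree**, F−1
edges).  Enumeration runs over skeleton trees; by the matrix-tree
theorem their total is the determinant of a reduced face-graph
Laplacian, and two trees give the *same* net when a symmetry of the
solid (rotation or reflection) maps one onto the other.  Reducing the
5,184,000 spanning trees of the dodecahedron or icosahedron by the full
symmetry group of order 120 leaves **43,380 distinct nets** each
(tetrahedron 2, cube 11, octahedron 11).

Per net, the package computes seven foldability descriptors:

- **vertex connections** — net vertices already incident to every face
  they touch on the solid (net degree m+1, with m faces per solid
  vertex); one edge-gluing closes the polyhedron locally there.  A
  *traditional* wider definition (two faces sharing a vertex but not an
  edge) is also provided;
- **leaves** — faces hinged by a single edge (skeleton degree 1);
- **spanning-tree length** (F−1) and **degree distribution** — counts
  (A, B, C, …) of skeleton nodes by degree, constrained by
  ΣA = F and Σd·A_d = 2(F−1);
- **backbone** — the skeleton-tree diameter in edges;
- **radius of gyration** Rg with unit edges,
  Rg² = (1/N) Σᵢ ((xᵢ−x̄)² + (yᵢ−ȳ)²) over face centroids (an exact
  area-integral variant is also implemented);
- **convex-hull area and perimeter** of the net.

The boundary of every net is the Euler tour of its doubled cutting tree:
a cyclic sequence of 2(V−1) vertex degrees that serves as a printable
net identifier.

## Worked example

```python
import durernet as dn

ico = dn.build_platonic("icosahedron")          # V=12, E=30, F=20, unit edges
census = dn.net_census(ico)                     # full enumeration + symmetry
print(census.tree_count, census.net_count)      # 5184000 43380

circuit = (2,3,6,3,2,6,5,2,5,2,5,2,3,6,3,2,6,5,2,5,2,5)
net = dn.find_net_by_circuit(ico, circuit, census)
print(len(net.boundary))                        # 22  (= 2(V-1) boundary vertices)
print(dn.vertex_connections(net, "restrictive"))  # 4
print(dn.leaves(net))                           # 8
print(dn.overlap_check(net))                    # False
```

The 22-stop boundary degree circuit picks out exactly one of the 43,380
icosahedron nets; it has 4 vertex connections (degree-6 net vertices)
and 8 leaf faces.

Study-level analysis on the dodecahedron:

```python
from durernet.analysis import correlate, descriptor_table

dod = dn.build_platonic("dodecahedron")
table = descriptor_table(dod)                   # 43,380 rows, one per net
r = correlate(table["hull_perimeter"], table["rg"])
print(round(r.r_squared, 3))                    # 0.738
r = correlate(table["hull_area"], table["rg"])
print(round(r.r_squared, 3))                    # 0.141
```

Hull *perimeter* tracks the radius of gyration closely (R² ≈ 0.74) while
hull *area* does not (R² ≈ 0.14): perimeter and Rg measure the same
"spherical" compactness, area a different, elongation-sensitive one.

A `durernet` CLI wraps the same pipeline
(`enumerate`, `describe`, `report`, `correlate`, `sample`, `render`,
`magnet-map`), e.g. `durernet report --solid cube`.

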