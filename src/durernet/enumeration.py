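"""Enumeration and unfolding of Dürer nets.

A Dürer net is a planar, single-piece, non-self-overlapping edge
unfolding of a convex polyhedron.  Cutting along a spanning tree of the
polyhedron's vertices (the *cutting tree*) flattens the surface; dually,
the faces that remain hinged together form a spanning tree of the
face-adjacency graph (the *skeleton tree*).  Enumeration therefore runs
over skeleton trees, which is where all downstream descriptors live, and
derives the cutting tree by complement duality.

Two nets are the same configuration when a symmetry of the solid maps
one set of cuts onto the other; distinct nets are orbit representatives
under the full symmetry group (rotations and reflections — the
convention under which the classical counts 2/11/11/43,380/43,380 for
the Platonic solids are reproduced).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Hashable, Iterator, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np

from . import _treegen
from .polyhedra import Polyhedron, SymmetryGroup, face_permutation, symmetry_group

__all__ = [
    "SkeletonTree",
    "CutTree",
    "DurerNet",
    "BoundaryVertex",
    "CanonicalID",
    "NetCensus",
    "UnfoldError",
    "enumerate_skeleton_trees",
    "skeleton_to_cut_tree",
    "unfold",
    "overlap_check",
    "boundary_circuit",
    "canonical_id",
    "canonical_circuit",
    "net_census",
    "enumerate_nets",
    "find_net_by_circuit",
    "make_fixture",
    "spanning_tree_count",
]

#: vertex-coincidence tolerance for unfolded coordinates
UNFOLD_TOL = 1e-9

#: fractional shrink applied to faces before the overlap test, so faces
#: meeting only in shared edges or vertices never register as overlapping
OVERLAP_SHRINK = 1e-7


class UnfoldError(RuntimeError):
    """Raised when face placement degenerates during unfolding."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SkeletonTree:
    """Spanning tree of the face-adjacency graph: the net's fold hinges.

    ``nodes`` are face indices; ``edges`` are unordered face pairs that
    stay folded (uncut).  For a solid with F faces a spanning skeleton
    has ``e = F - 1`` edges and degree sum ``2e``.
    """

    nodes: tuple[int, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))
        object.__setattr__(
            self, "edges", frozenset(tuple(sorted(e)) for e in self.edges)
        )
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError(
                f"tree on {len(self.nodes)} nodes must have {len(self.nodes) - 1} "
                f"edges, got {len(self.edges)}"
            )
        if not _is_spanning_forestless(self.nodes, self.edges):
            raise ValueError("edge set is not a spanning tree (cycle or disconnect)")

    def degree(self, node: int) -> int:
        return sum(node in e for e in self.edges)

    @property
    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {n: [] for n in self.nodes}
        for a, b in sorted(self.edges):
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass(frozen=True)
class CutTree:
    """Spanning tree of the polyhedron's vertices: the cut edges."""

    nodes: tuple[int, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))
        object.__setattr__(
            self, "edges", frozenset(tuple(sorted(e)) for e in self.edges)
        )
        if len(self.edges) != len(self.nodes) - 1:
            raise ValueError("cut tree must have V - 1 edges")
        if not _is_spanning_forestless(self.nodes, self.edges):
            raise ValueError("cut edges do not form a spanning tree")

    def degree(self, node: int) -> int:
        return sum(node in e for e in self.edges)


def _is_spanning_forestless(nodes: Sequence[int], edges) -> bool:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges = 0
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            return False
        parent[ra] = rb
        merges += 1
    return merges == len(nodes) - 1


# ---------------------------------------------------------------------------
# Nets
# ---------------------------------------------------------------------------


class BoundaryVertex(NamedTuple):
    """One stop on the net's boundary circuit."""

    net_vertex: int
    solid_vertex: Hashable
    degree: int


@dataclass(frozen=True, eq=False)
class DurerNet:
    """A planar unfolding: per-face polygons plus provenance.

    ``faces`` maps each face index to its placed 2D polygon (vertices in
    the face's cycle order, unit edges).  ``boundary`` is the cyclic
    sequence of boundary net vertices with their net degrees — for a
    spanning net this is the Euler tour of the doubled cutting tree and
    has length ``2(V - 1)``.
    """

    solid: Polyhedron | None
    faces: tuple[tuple[int, np.ndarray], ...]
    skeleton: SkeletonTree
    cut_tree: CutTree | None
    boundary: tuple[BoundaryVertex, ...]
    net_vertex_coords: dict[int, np.ndarray] = field(repr=False)
    net_vertex_solid: dict[int, Hashable] = field(repr=False)

    def __post_init__(self) -> None:
        if self.solid is not None and self.cut_tree is not None:
            expect = 2 * (self.solid.vertex_count - 1)
            if len(self.boundary) != expect:
                raise ValueError(
                    f"boundary circuit has {len(self.boundary)} stops, "
                    f"expected 2(V-1) = {expect}"
                )

    @property
    def face_count(self) -> int:
        return len(self.faces)

    @property
    def face_centroids(self) -> np.ndarray:
        return np.stack([poly.mean(axis=0) for _, poly in self.faces])

    @property
    def all_vertices(self) -> np.ndarray:
        return np.concatenate([poly for _, poly in self.faces])


@dataclass(frozen=True)
class CanonicalID:
    """Label-free identifier of a net.

    ``orbit_key`` is the skeleton edge set minimized over the solid's full
    symmetry group: equal exactly for symmetry-equivalent nets.
    ``degree_circuit`` is the lexicographically minimal cyclic form (both
    traversal directions) of the boundary degree sequence — the field's
    printable net identifier, whose uniqueness is measured, not assumed.
    """

    orbit_key: tuple[tuple[int, int], ...]
    degree_circuit: tuple[int, ...]


# ---------------------------------------------------------------------------
# Skeleton-tree enumeration
# ---------------------------------------------------------------------------


def _face_edge_list(p: Polyhedron) -> tuple[tuple[int, int], ...]:
    return tuple(fg for fg, _ in p.face_adjacency)


def spanning_tree_count(graph: nx.Graph) -> int:
    """Exact matrix-tree (Kirchhoff) spanning-tree count of a graph."""
    nodes = {n: i for i, n in enumerate(graph.nodes)}
    edges = [(nodes[a], nodes[b]) for a, b in graph.edges]
    return _treegen.spanning_tree_count(edges, len(nodes))


def enumerate_skeleton_trees(p: Polyhedron) -> Iterator[SkeletonTree]:
    """Stream every spanning tree of the face-adjacency graph exactly once.

    The total count equals the matrix-tree determinant of the face graph
    (checked in the test suite; 5,184,000 for the dodecahedron and the
    icosahedron).
    """
    if not nx.is_connected(p.face_graph):
        raise ValueError(f"{p.name}: face-adjacency graph is disconnected")
    edges = _face_edge_list(p)
    nodes = tuple(range(len(p.faces)))
    for mask in _treegen.spanning_tree_masks(list(edges), len(nodes)):
        yield SkeletonTree(nodes=nodes, edges=_treegen.mask_to_edges(mask, list(edges)))


def skeleton_to_cut_tree(p: Polyhedron, t: SkeletonTree) -> CutTree:
    """Complement duality: an edge is cut iff its fold hinge is absent.

    The solid edges whose face-adjacency edge is not in the skeleton tree
    form a spanning tree of the polyhedron's vertices (V - 1 edges).
    """
    cut = [
        solid_edge
        for fg, solid_edge in p.face_adjacency
        if fg not in t.edges
    ]
    return CutTree(nodes=tuple(range(p.vertex_count)), edges=frozenset(cut))


# ---------------------------------------------------------------------------
# Unfolding
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _unfold_context(p: Polyhedron):
    """Per-solid geometry: local face frames and hinge motions.

    Each face is embedded in 2D (complex plane) in its own frame,
    counterclockwise as seen from outside, centroid at the origin.  For
    every directed face adjacency (f, g) the rigid motion z -> a z + b
    maps g's frame into f's frame so that the shared edge coincides and g
    lies on the far side — rotations only, since consistently oriented
    faces traverse a shared edge in opposite directions.
    """
    loc: list[np.ndarray] = []
    for f in p.faces:
        pts = p.vertices[list(f)]
        c = pts.mean(axis=0)
        n = np.cross(pts[1] - pts[0], pts[2] - pts[1])
        n = n / np.linalg.norm(n)
        a = pts[0] - c
        a = a / np.linalg.norm(a)
        b = np.cross(n, a)
        xy = (pts - c) @ np.stack([a, b]).T
        loc.append(xy[:, 0] + 1j * xy[:, 1])
    motions: dict[tuple[int, int], tuple[complex, complex]] = {}
    for (f, g), (a, b) in p.face_adjacency:
        for src, dst in ((g, f), (f, g)):
            pa = loc[dst][p.faces[dst].index(a)]
            pb = loc[dst][p.faces[dst].index(b)]
            qa = loc[src][p.faces[src].index(a)]
            qb = loc[src][p.faces[src].index(b)]
            alpha = (pa - pb) / (qa - qb)
            beta = pa - alpha * qa
            motions[(dst, src)] = (alpha, beta)
    shared: dict[tuple[int, int], tuple[int, int]] = {
        fg: e for fg, e in p.face_adjacency
    }
    return loc, motions, shared


def _place_faces(
    p: Polyhedron, t: SkeletonTree, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-face placement motions (alpha, beta) for the skeleton tree.

    Root face = lowest face index in the tree; its centroid sits at the
    origin and its first edge points along +x.
    """
    loc, motions, _ = _unfold_context(p)
    F = len(p.faces)
    adj = t.adjacency
    root = t.nodes[0]
    al = np.zeros(F, complex)
    be = np.zeros(F, complex)
    al[root] = 1.0
    seen = {root}
    stack = [root]
    while stack:
        f = stack.pop()
        for g in adj[f]:
            if g not in seen:
                seen.add(g)
                a, b = motions[(f, g)]
                al[g] = al[f] * a
                be[g] = al[f] * b + be[f]
                stack.append(g)
    # canonical in-plane pose: root first edge along +x
    e = loc[root][1] - loc[root][0]
    rot = np.conj(e) / abs(e)
    al *= rot
    be *= rot
    # degeneracy check: shared edges of folded faces must coincide
    for f, g in t.edges:
        a, b = _unfold_context(p)[2][(f, g)]
        for v in (a, b):
            zf = al[f] * loc[f][p.faces[f].index(v)] + be[f]
            zg = al[g] * loc[g][p.faces[g].index(v)] + be[g]
            if abs(zf - zg) > max(tol, 1e-12):
                raise UnfoldError(
                    f"faces {f} and {g} separate at solid vertex {v}: "
                    f"|dz| = {abs(zf - zg):.3e}"
                )
    return al, be


def _assemble_net(
    face_cycles: Mapping[int, tuple[Hashable, ...]],
    face_polys: Mapping[int, np.ndarray],
    skeleton: SkeletonTree,
    folded_labels: Mapping[tuple[int, int], tuple[Hashable, Hashable]],
    solid: Polyhedron | None,
    cut_tree: CutTree | None,
) -> DurerNet:
    """Identify net vertices, compute net degrees, and walk the boundary.

    Works for spanning nets, partial nets and synthetic fixtures alike:
    all it needs is each face's vertex-label cycle, its planar polygon in
    matching order, and which labelled edges are folded.
    """
    # union-find over (face, label) incidences, merged across fold edges
    parent: dict[tuple[int, Hashable], tuple[int, Hashable]] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for fi in sorted(face_cycles):
        for lab in face_cycles[fi]:
            parent[(fi, lab)] = (fi, lab)
    for (f, g) in sorted(skeleton.edges):
        a, b = folded_labels[(f, g)]
        for lab in (a, b):
            ra, rb = find((f, lab)), find((g, lab))
            if ra != rb:
                parent[ra] = rb

    ids: dict[tuple[int, Hashable], int] = {}
    coords: dict[int, np.ndarray] = {}
    solid_of: dict[int, Hashable] = {}
    for fi in sorted(face_cycles):
        cyc = face_cycles[fi]
        poly = face_polys[fi]
        for slot, lab in enumerate(cyc):
            r = find((fi, lab))
            if r not in ids:
                ids[r] = len(ids)
                coords[ids[r]] = poly[slot].copy()
                solid_of[ids[r]] = lab
    nid = lambda f, lab: ids[find((f, lab))]

    folded_slots: set[tuple[int, frozenset]] = set()
    for e in skeleton.edges:
        f, g = tuple(sorted(e))
        lab = frozenset(folded_labels[(f, g)])
        folded_slots.add((f, lab))
        folded_slots.add((g, lab))
    degree: dict[int, int] = dict.fromkeys(ids.values(), 0)
    nxt: dict[int, int] = {}
    for f, g in skeleton.edges:
        a, b = folded_labels[(f, g)]
        degree[nid(f, a)] += 1
        degree[nid(f, b)] += 1
    for fi in sorted(face_cycles):
        cyc = face_cycles[fi]
        k = len(cyc)
        for i in range(k):
            a, b = cyc[i], cyc[(i + 1) % k]
            if (fi, frozenset((a, b))) in folded_slots:
                continue
            u, v = nid(fi, a), nid(fi, b)
            degree[u] += 1
            degree[v] += 1
            nxt[u] = v  # boundary directed along the face orientation
    # each boundary edge contributes to both endpoints but was counted
    # twice above only for fold edges; boundary edges were counted once at
    # each endpoint, fold edges once at each endpoint too -- degrees final.

    boundary: list[BoundaryVertex] = []
    if nxt:
        start = min(nxt)
        v = start
        for _ in range(len(nxt) + 1):
            boundary.append(BoundaryVertex(v, solid_of[v], degree[v]))
            v = nxt[v]
            if v == start:
                break
        else:
            raise UnfoldError("net boundary is not a single closed circuit")

    faces_out = tuple(
        (fi, np.asarray(face_polys[fi], float)) for fi in sorted(face_cycles)
    )
    return DurerNet(
        solid=solid,
        faces=faces_out,
        skeleton=skeleton,
        cut_tree=cut_tree,
        boundary=tuple(boundary),
        net_vertex_coords=coords,
        net_vertex_solid=solid_of,
    )


def unfold(p: Polyhedron, t: SkeletonTree, tol: float = UNFOLD_TOL) -> DurerNet:
    """Unfold a skeleton tree into its planar Dürer net.

    Traverses the tree from the root face, placing each face by the rigid
    motion that maps its shared edge onto the already-placed twin.  The
    resulting net has unit-edge faces congruent to the solid's, and its
    boundary circuit is the Euler tour of the doubled cutting tree.
    """
    loc, _, shared = _unfold_context(p)
    al, be = _place_faces(p, t, tol)
    spanning = len(t.nodes) == len(p.faces)
    cycles = {f: p.faces[f] for f in t.nodes}
    polys = {}
    for f in t.nodes:
        z = al[f] * loc[f] + be[f]
        polys[f] = np.stack([z.real, z.imag], axis=1)
    folded = {fg: shared[fg] for fg in (tuple(sorted(e)) for e in t.edges)}
    cut = skeleton_to_cut_tree(p, t) if spanning else None
    return _assemble_net(cycles, polys, t, folded, p, cut)


# ---------------------------------------------------------------------------
# Net-level operations
# ---------------------------------------------------------------------------


def overlap_check(net: DurerNet, shrink: float = OVERLAP_SHRINK) -> bool:
    """True iff two face interiors of the net intersect.

    Faces are shrunk toward their centroids by ``shrink`` before testing,
    so exact shared edges and shared vertices never count as overlap
    (O'Rourke's property 4 concerns interiors).
    """
    from shapely import STRtree
    from shapely.geometry import Polygon

    polys = []
    for _, poly in net.faces:
        c = poly.mean(axis=0)
        polys.append(Polygon(c + (poly - c) * (1.0 - shrink)))
    tree = STRtree(polys)
    for i, pg in enumerate(polys):
        for j in tree.query(pg, predicate="intersects"):
            if int(j) > i:
                return True
    return False


def boundary_circuit(net: DurerNet) -> tuple[int, ...]:
    """Cyclic sequence of net-vertex degrees along the outer boundary.

    For a spanning net this is the Euler tour of the doubled cutting
    tree: length 2(V - 1), each boundary vertex reported with its net
    degree (folded plus boundary edges).
    """
    return tuple(bv.degree for bv in net.boundary)


def canonical_circuit(seq: Sequence[int]) -> tuple[int, ...]:
    """Lexicographically minimal rotation of ``seq`` in either direction."""
    seq = tuple(seq)
    if not seq:
        return seq
    n = len(seq)
    best = None
    for s in (seq, seq[::-1]):
        doubled = s + s
        for r in range(n):
            cand = doubled[r : r + n]
            if best is None or cand < best:
                best = cand
    return best


@lru_cache(maxsize=32)
def _full_group(p: Polyhedron) -> SymmetryGroup:
    return symmetry_group(p, include_reflections=True)


@lru_cache(maxsize=32)
def _face_perms(p: Polyhedron) -> tuple[tuple[int, ...], ...]:
    return tuple(face_permutation(p, g) for g in _full_group(p))


def canonical_id(p: Polyhedron, net: DurerNet) -> CanonicalID:
    """Symmetry-invariant identifier of a net.

    The orbit key is the minimal image of the skeleton edge set over the
    solid's full symmetry group (rotations and reflections), so mirror
    images and relabelings by any symmetry share the same key.
    """
    edges = net.skeleton.edges
    best = None
    for fp in _face_perms(p):
        img = tuple(sorted(tuple(sorted((fp[a], fp[b]))) for a, b in edges))
        if best is None or img < best:
            best = img
    return CanonicalID(
        orbit_key=best, degree_circuit=canonical_circuit(boundary_circuit(net))
    )


# ---------------------------------------------------------------------------
# Full enumeration with symmetry reduction
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class NetCensus:
    """Exhaustive enumeration result for one solid.

    ``canonical_masks`` are one skeleton-tree bitmask per distinct net
    (minimal image over the full symmetry group); ``orbit_sizes`` are the
    number of raw spanning trees in each orbit and sum to ``tree_count``.
    """

    solid: Polyhedron
    edge_list: tuple[tuple[int, int], ...]
    tree_count: int
    canonical_masks: np.ndarray
    orbit_sizes: np.ndarray
    group_order: int

    @property
    def net_count(self) -> int:
        return len(self.canonical_masks)

    def skeleton_tree(self, mask: int) -> SkeletonTree:
        return SkeletonTree(
            nodes=tuple(range(len(self.solid.faces))),
            edges=_treegen.mask_to_edges(int(mask), list(self.edge_list)),
        )


def net_census(p: Polyhedron, cache_path: str | Path | None = None) -> NetCensus:
    """Enumerate all spanning trees and reduce them to distinct nets.

    Optionally persists the result to ``cache_path`` (.npz) and reloads
    it on a rerun, which makes interrupted large runs resumable.
    """
    edges = _face_edge_list(p)
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            data = np.load(cache_path)
            return NetCensus(
                solid=p,
                edge_list=edges,
                tree_count=int(data["tree_count"]),
                canonical_masks=data["canonical_masks"],
                orbit_sizes=data["orbit_sizes"],
                group_order=int(data["group_order"]),
            )
    if not nx.is_connected(p.face_graph):
        raise ValueError(f"{p.name}: face-adjacency graph is disconnected")
    masks = _treegen.spanning_tree_masks(list(edges), len(p.faces))
    eidx = {e: i for i, e in enumerate(edges)}
    perms = []
    for fp in _face_perms(p):
        perms.append(
            [eidx[tuple(sorted((fp[a], fp[b])))] for a, b in edges]
        )
    canon, sizes = _treegen.canonical_reduce(masks, np.asarray(perms))
    census = NetCensus(
        solid=p,
        edge_list=edges,
        tree_count=len(masks),
        canonical_masks=canon,
        orbit_sizes=sizes,
        group_order=len(perms),
    )
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            cache_path,
            tree_count=census.tree_count,
            canonical_masks=census.canonical_masks,
            orbit_sizes=census.orbit_sizes,
            group_order=census.group_order,
        )
    return census


def enumerate_nets(
    p: Polyhedron, census: NetCensus | None = None
) -> Iterator[DurerNet]:
    """Yield one unfolded Dürer net per symmetry orbit of skeleton trees.

    The number of nets matches the classical counts (tetrahedron 2, cube
    11, octahedron 11, dodecahedron 43,380, icosahedron 43,380), and the
    orbit sizes sum to the solid's total spanning-tree count.
    """
    if census is None:
        census = net_census(p)
    for mask in census.canonical_masks:
        yield unfold(p, census.skeleton_tree(int(mask)))


def find_net_by_circuit(
    p: Polyhedron,
    circuit: Sequence[int],
    census: NetCensus | None = None,
) -> DurerNet | None:
    """Locate the distinct net whose boundary degree circuit matches.

    The query circuit is compared in canonical cyclic form (minimal
    rotation, either direction), so any starting vertex and traversal
    direction of a printed circuit will match.  Returns None when no
    distinct net realizes the circuit.
    """
    target = canonical_circuit(circuit)
    if census is None:
        census = net_census(p)
    for mask in census.canonical_masks:
        net = unfold(p, census.skeleton_tree(int(mask)))
        if canonical_circuit(boundary_circuit(net)) == target:
            return net
    return None


# ---------------------------------------------------------------------------
# Adversarial / synthetic fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, **params) -> DurerNet:
    """Construct synthetic pseudo-nets for negative and edge-case tests.

    ``overlapping_fan(n)``: n >= 7 unit triangles fanned around one shared
    vertex — 60° each, so the angular sum exceeds 360° and face interiors
    overlap (violates the non-self-overlap property).
    ``chain_net(n)``: n unit squares in a row — path skeleton, 2 leaves,
    diameter n - 1.
    ``star_net(k)``: a regular k-gon with a congruent k-gon glued to every
    edge — star skeleton, k leaves, diameter 2.
    """
    if kind == "overlapping_fan":
        n = int(params.pop("n", 7))
        _reject_params(params)
        if n < 7:
            raise ValueError(
                f"overlapping_fan needs n >= 7 triangles to overlap, got {n}"
            )
        return _fan_fixture(n)
    if kind == "chain_net":
        n = int(params.pop("n", 6))
        _reject_params(params)
        if n < 2:
            raise ValueError("chain_net needs at least 2 faces")
        return _chain_fixture(n)
    if kind == "star_net":
        k = int(params.pop("k", 5))
        _reject_params(params)
        if k < 3:
            raise ValueError("star_net needs a k-gon with k >= 3")
        return _star_fixture(k)
    raise ValueError(
        f"unknown fixture kind {kind!r}; expected overlapping_fan, chain_net "
        "or star_net"
    )


def _reject_params(params: dict) -> None:
    if params:
        raise ValueError(f"unknown fixture parameters: {sorted(params)}")


def _fan_fixture(n: int) -> DurerNet:
    cycles = {}
    polys = {}
    folded = {}
    for i in range(n):
        a = math.radians(60 * i)
        b = math.radians(60 * (i + 1))
        cycles[i] = ("c", f"r{i}", f"r{i + 1}")
        polys[i] = np.array(
            [[0.0, 0.0], [math.cos(a), math.sin(a)], [math.cos(b), math.sin(b)]]
        )
        if i:
            folded[(i - 1, i)] = ("c", f"r{i}")
    tree = SkeletonTree(
        nodes=tuple(range(n)), edges=frozenset((i - 1, i) for i in range(1, n))
    )
    return _assemble_net(cycles, polys, tree, folded, None, None)


def _chain_fixture(n: int) -> DurerNet:
    cycles = {}
    polys = {}
    folded = {}
    for i in range(n):
        cycles[i] = ((i, 0), (i + 1, 0), (i + 1, 1), (i, 1))
        polys[i] = np.array(
            [[i, 0.0], [i + 1.0, 0.0], [i + 1.0, 1.0], [i, 1.0]]
        )
        if i:
            folded[(i - 1, i)] = ((i, 0), (i, 1))
    tree = SkeletonTree(
        nodes=tuple(range(n)), edges=frozenset((i - 1, i) for i in range(1, n))
    )
    return _assemble_net(cycles, polys, tree, folded, None, None)


def _star_fixture(k: int) -> DurerNet:
    # central regular k-gon with unit edges, CCW
    R = 0.5 / math.sin(math.pi / k)
    core = np.array(
        [
            [R * math.cos(2 * math.pi * (i + 0.5) / k), R * math.sin(2 * math.pi * (i + 0.5) / k)]
            for i in range(k)
        ]
    )
    cycles = {0: tuple(("c", i) for i in range(k))}
    polys = {0: core}
    folded = {}
    for i in range(k):
        a = core[i]
        b = core[(i + 1) % k]
        mid = (a + b) / 2.0
        # point reflection through the edge midpoint glues a congruent
        # k-gon to the far side, traversing the shared edge oppositely
        mirror = 2 * mid - core
        labels = tuple(
            ("c", (i + 1) % k) if j == i
            else ("c", i) if j == (i + 1) % k
            else (i, j)
            for j in range(k)
        )
        cycles[i + 1] = labels
        polys[i + 1] = mirror
        folded[(0, i + 1)] = (("c", i), ("c", (i + 1) % k))
    tree = SkeletonTree(
        nodes=tuple(range(k + 1)), edges=frozenset((0, i + 1) for i in range(k))
    )
    return _assemble_net(cycles, polys, tree, folded, None, None)
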