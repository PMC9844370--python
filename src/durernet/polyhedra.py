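"""Convex polyhedra with unit edges, their symmetry groups, and capsid geometry.

The five Platonic solids are the built-in substrates for net enumeration:
an icosahedral T=1 viral capsid has 20 triangular capsomere faces, so the
icosahedron (and its dual, the dodecahedron) are the biologically motivated
cases, with the tetrahedron, cube and octahedron as small controls.

All solids are normalized to edge length exactly 1 so that downstream
geometric descriptors (radius of gyration, convex-hull area/perimeter) are
comparable between solids and between studies.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Polyhedron",
    "SymmetryGroup",
    "EdgeMagnetAssignment",
    "MagnetReport",
    "TNumber",
    "PLATONIC_NAMES",
    "build_platonic",
    "symmetry_group",
    "schlegel_layout",
    "magnet_map",
    "validate_magnet_map",
    "enantiomer",
    "triangulation_number",
]

PLATONIC_NAMES = ("tetrahedron", "cube", "octahedron", "dodecahedron", "icosahedron")

_PHI = (1.0 + math.sqrt(5.0)) / 2.0

#: geometric tolerance for unit edge lengths and coincident vertices
GEOM_TOL = 1e-9


class PolyhedronError(ValueError):
    """Raised when a mesh violates the closed-convex-surface invariants."""


@dataclass(frozen=True, eq=False)
class Polyhedron:
    """A closed convex polyhedron with unit edge length.

    Parameters
    ----------
    name:
        Label, e.g. ``"icosahedron"`` or the stem of an OFF file.
    vertices:
        ``(V, 3)`` float array.  Every edge must have length 1 within
        :data:`GEOM_TOL`.
    faces:
        Oriented vertex-index cycles, all counterclockwise as seen from
        outside, so that every edge is traversed once in each direction.
    """

    name: str
    vertices: np.ndarray
    faces: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, float))
        object.__setattr__(self, "faces", tuple(tuple(map(int, f)) for f in self.faces))
        self._validate()

    # -- invariants -----------------------------------------------------

    def _validate(self) -> None:
        V, E, F = self.vertex_count, len(self.edges), len(self.faces)
        if V - E + F != 2:
            raise PolyhedronError(
                f"{self.name}: Euler characteristic V-E+F = {V - E + F}, expected 2"
            )
        for a, b in self.edges:
            length = float(np.linalg.norm(self.vertices[a] - self.vertices[b]))
            if abs(length - 1.0) > GEOM_TOL:
                raise PolyhedronError(
                    f"{self.name}: edge {(a, b)} has length {length!r}, expected 1"
                )
        # each directed edge must appear exactly once => every undirected
        # edge is shared by exactly two consistently oriented faces
        directed: set[tuple[int, int]] = set()
        for f in self.faces:
            if len(set(f)) != len(f):
                raise PolyhedronError(f"{self.name}: face {f} repeats a vertex")
            for a, b in _cycle_pairs(f):
                if (a, b) in directed:
                    raise PolyhedronError(
                        f"{self.name}: directed edge {(a, b)} traversed twice; "
                        "faces are not consistently oriented"
                    )
                directed.add((a, b))
        for a, b in directed:
            if (b, a) not in directed:
                raise PolyhedronError(
                    f"{self.name}: edge {(a, b)} is not shared by two faces"
                )

    # -- derived combinatorics ------------------------------------------

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @cached_property
    def edges(self) -> tuple[tuple[int, int], ...]:
        """Sorted undirected vertex-index pairs."""
        es = {tuple(sorted((a, b))) for f in self.faces for a, b in _cycle_pairs(f)}
        return tuple(sorted(es))

    @cached_property
    def edge_index(self) -> dict[tuple[int, int], int]:
        return {e: i for i, e in enumerate(self.edges)}

    @cached_property
    def face_adjacency(self) -> tuple[tuple[tuple[int, int], tuple[int, int]], ...]:
        """Pairs ``((f, g), (a, b))``: faces f < g share solid edge (a, b)."""
        owner: dict[tuple[int, int], int] = {}
        out = []
        for fi, f in enumerate(self.faces):
            for a, b in _cycle_pairs(f):
                e = (a, b) if a < b else (b, a)
                if e in owner:
                    out.append((tuple(sorted((owner[e], fi))), e))
                else:
                    owner[e] = fi
        out.sort()
        return tuple(out)

    @cached_property
    def graph(self) -> nx.Graph:
        """The 1-skeleton (vertices and edges) as a networkx graph."""
        g = nx.Graph()
        g.add_nodes_from(range(self.vertex_count))
        g.add_edges_from(self.edges)
        return g

    @cached_property
    def face_graph(self) -> nx.Graph:
        """Face-adjacency graph: nodes are faces, edges are fold hinges."""
        g = nx.Graph()
        g.add_nodes_from(range(len(self.faces)))
        g.add_edges_from(fg for fg, _ in self.face_adjacency)
        return g

    @cached_property
    def vertex_successor(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Rotation system: ``(w, a) -> (b, f)``.

        Crossing face ``f`` (the face ``... a, w, b ...``) rotates the edge
        ``(w, a)`` to the next edge ``(w, b)`` around vertex ``w``, in the
        consistent orientation induced by the face cycles.  This is the
        combinatorial structure behind boundary circuits of nets.
        """
        succ: dict[tuple[int, int], tuple[int, int]] = {}
        for fi, f in enumerate(self.faces):
            k = len(f)
            for i, w in enumerate(f):
                a = f[(i - 1) % k]
                b = f[(i + 1) % k]
                succ[(w, a)] = (b, fi)
        return succ

    @cached_property
    def vertex_face_count(self) -> tuple[int, ...]:
        """Number of faces meeting at each vertex (m in the text)."""
        cnt = [0] * self.vertex_count
        for f in self.faces:
            for v in f:
                cnt[v] += 1
        return tuple(cnt)


def _cycle_pairs(cycle: Sequence[int]) -> Iterable[tuple[int, int]]:
    n = len(cycle)
    return ((cycle[i], cycle[(i + 1) % n]) for i in range(n))


# ---------------------------------------------------------------------------
# Platonic solid construction
# ---------------------------------------------------------------------------


def _platonic_vertices(name: str) -> np.ndarray:
    if name == "tetrahedron":
        v = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    elif name == "cube":
        v = list(itertools.product((-1, 1), repeat=3))
    elif name == "octahedron":
        v = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    elif name == "dodecahedron":
        v = list(itertools.product((-1, 1), repeat=3))
        for a, b in itertools.product((-1, 1), repeat=2):
            v += [
                (0, a / _PHI, b * _PHI),
                (a / _PHI, b * _PHI, 0),
                (a * _PHI, 0, b / _PHI),
            ]
    elif name == "icosahedron":
        v = []
        for a, b in itertools.product((-1, 1), repeat=2):
            v += [(0, a, b * _PHI), (a, b * _PHI, 0), (a * _PHI, 0, b)]
    else:
        raise ValueError(
            f"unknown Platonic solid {name!r}; expected one of {PLATONIC_NAMES}"
        )
    return np.asarray(v, float)


def faces_from_convex_hull(vertices: np.ndarray) -> tuple[tuple[int, ...], ...]:
    """Oriented face cycles of the convex hull of ``vertices``.

    Qhull triangulates, so coplanar simplices are merged by supporting
    plane and each merged face is ordered counterclockwise around its
    centroid as seen from outside (along the outward normal).
    """
    from scipy.spatial import ConvexHull

    hull = ConvexHull(vertices)
    planes: dict[tuple, tuple[np.ndarray, set[int]]] = {}
    for simplex, eq in zip(hull.simplices, hull.equations):
        key = tuple(np.round(eq, 6))
        planes.setdefault(key, (np.asarray(eq[:3]), set()))[1].update(map(int, simplex))
    faces = []
    for normal, vs in planes.values():
        vs = sorted(vs)
        c = vertices[vs].mean(axis=0)
        a = vertices[vs[0]] - c
        a = a / np.linalg.norm(a)
        b = np.cross(normal / np.linalg.norm(normal), a)
        ang = [
            math.atan2(float((vertices[i] - c) @ b), float((vertices[i] - c) @ a))
            for i in vs
        ]
        faces.append(tuple(v for _, v in sorted(zip(ang, vs))))
    return tuple(sorted(faces))


def build_platonic(name: str) -> Polyhedron:
    """Construct a Platonic solid with unit edge length.

    >>> build_platonic("icosahedron").vertex_count
    12
    """
    name = name.strip().lower()
    verts = _platonic_vertices(name)
    faces = faces_from_convex_hull(verts)
    lengths = [
        np.linalg.norm(verts[a] - verts[b]) for f in faces for a, b in _cycle_pairs(f)
    ]
    verts = verts / min(lengths)
    # snap edge lengths to exactly 1 within floating tolerance
    return Polyhedron(name=name, vertices=verts, faces=faces)


# ---------------------------------------------------------------------------
# Symmetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymmetryGroup:
    """A group of vertex permutations preserving edges and faces."""

    permutations: tuple[tuple[int, ...], ...]
    includes_reflections: bool

    @property
    def order(self) -> int:
        return len(self.permutations)

    def __iter__(self):
        return iter(self.permutations)

    def validate(self, p: Polyhedron) -> None:
        """Check closure, identity, and edge/face preservation."""
        perms = set(self.permutations)
        n = p.vertex_count
        if tuple(range(n)) not in perms:
            raise ValueError("group does not contain the identity")
        edges = set(p.edges)
        face_sets = {frozenset(f) for f in p.faces}
        for g in perms:
            for a, b in p.edges:
                if tuple(sorted((g[a], g[b]))) not in edges:
                    raise ValueError("group element does not preserve edges")
            for f in p.faces:
                if frozenset(g[v] for v in f) not in face_sets:
                    raise ValueError("group element does not preserve faces")
        for g in self.permutations:
            for h in self.permutations:
                if tuple(g[h[i]] for i in range(n)) not in perms:
                    raise ValueError("group is not closed under composition")


def _automorphisms(p: Polyhedron) -> list[tuple[int, ...]]:
    """All vertex bijections preserving adjacency and the face set.

    Plain backtracking in BFS vertex order, so each placement is pruned by
    at least one already-placed neighbor; fast for meshes of Platonic size.
    """
    n = p.vertex_count
    adj = [set() for _ in range(n)]
    for a, b in p.edges:
        adj[a].add(b)
        adj[b].add(a)
    deg = [len(s) for s in adj]
    face_sets = {frozenset(f) for f in p.faces}

    order = [0]
    seen = {0}
    qi = 0
    while len(order) < n:
        for nb in sorted(adj[order[qi]]):
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
        qi += 1

    perms: list[tuple[int, ...]] = []
    img: list[int | None] = [None] * n

    def extend(i: int) -> None:
        if i == n:
            perm = tuple(img)  # type: ignore[arg-type]
            for f in p.faces:
                if frozenset(perm[v] for v in f) not in face_sets:
                    return
            perms.append(perm)
            return
        v = order[i]
        used = {x for x in img if x is not None}
        cands = set(range(n)) - used
        for u in order[:i]:
            if u in adj[v]:
                cands &= adj[img[u]]  # type: ignore[index]
        for c in sorted(cands):
            if deg[c] == deg[v]:
                img[v] = c
                extend(i + 1)
                img[v] = None

    extend(0)
    return perms


def _preserves_orientation(perm: tuple[int, ...], p: Polyhedron) -> bool:
    """True if ``perm`` maps face cycles to rotations (not reversals)."""
    f0 = p.faces[0]
    image = tuple(perm[v] for v in f0)
    target = frozenset(image)
    for f in p.faces:
        if frozenset(f) == target:
            k = len(f)
            doubled = f + f
            return any(doubled[r : r + k] == image for r in range(k))
    raise AssertionError("image of a face is not a face")  # pragma: no cover


def symmetry_group(p: Polyhedron, include_reflections: bool = True) -> SymmetryGroup:
    """Combinatorial symmetry group of a polyhedron.

    Computed as the adjacency- and face-preserving vertex bijections of the
    mesh, so floating-point coordinates never enter the group structure.
    For the Platonic solids this coincides with the geometric symmetry
    group (orders 24/48/48/120/120 with reflections).  Asymmetric meshes
    yield the trivial group with a warning.
    """
    perms = _automorphisms(p)
    if not include_reflections:
        perms = [g for g in perms if _preserves_orientation(g, p)]
    if len(perms) == 1:
        warnings.warn(
            f"{p.name}: no nontrivial symmetries found; net counts will not "
            "be reduced",
            stacklevel=2,
        )
    return SymmetryGroup(
        permutations=tuple(sorted(perms)), includes_reflections=include_reflections
    )


def face_permutation(p: Polyhedron, perm: tuple[int, ...]) -> tuple[int, ...]:
    """The face permutation induced by a vertex permutation."""
    index = {frozenset(f): i for i, f in enumerate(p.faces)}
    return tuple(index[frozenset(perm[v] for v in f)] for f in p.faces)


# ---------------------------------------------------------------------------
# Schlegel layout
# ---------------------------------------------------------------------------


def schlegel_layout(p: Polyhedron, outer_face: int = 0) -> dict[int, np.ndarray]:
    """Planar straight-line drawing of the 1-skeleton (Tutte embedding).

    The chosen outer face is pinned to a regular polygon and every interior
    vertex is placed at the barycenter of its neighbors; for a 3-connected
    planar graph this is a crossing-free convex drawing (Tutte's theorem).
    The layout preserves exactly the face-adjacency topology used to read
    off which subunits bind, which is all a Schlegel diagram is used for
    here.
    """
    if not 0 <= outer_face < len(p.faces):
        raise IndexError(f"face index {outer_face} out of range")
    outer = p.faces[outer_face]
    n = p.vertex_count
    pos = np.zeros((n, 2))
    fixed = np.zeros(n, bool)
    for i, v in enumerate(outer):
        ang = 2 * math.pi * i / len(outer)
        pos[v] = (math.cos(ang), math.sin(ang))
        fixed[v] = True
    free = np.flatnonzero(~fixed)
    idx = {v: i for i, v in enumerate(free)}
    A = np.zeros((len(free), len(free)))
    rhs = np.zeros((len(free), 2))
    for i, v in enumerate(free):
        nbrs = list(p.graph.neighbors(v))
        A[i, i] = len(nbrs)
        for u in nbrs:
            if fixed[u]:
                rhs[i] += pos[u]
            else:
                A[i, idx[u]] -= 1.0
    if len(free):
        pos[free] = np.linalg.solve(A, rhs)
    return {v: pos[v].copy() for v in range(n)}


# ---------------------------------------------------------------------------
# Magnet maps (self-assembly design criteria as a validator)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeMagnetAssignment:
    """One ordered (N, S) pole pair per edge slot of each face.

    ``poles[(face, slot)]`` gives the pole pair laid along the face's
    counterclockwise traversal of its ``slot``-th edge.  With the same
    pattern on every identical subunit, any edge-to-edge contact between
    two subunits runs the two traversals in opposite directions, so a
    north pole always lands on a south pole: every contact attracts.
    """

    poles: Mapping[tuple[int, int], tuple[str, str]]

    def pair(self, face: int, slot: int) -> tuple[str, str]:
        return self.poles[(face, slot)]


@dataclass(frozen=True)
class MagnetReport:
    ok: bool
    violation: tuple[int, int] | None = None
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def magnet_map(p: Polyhedron) -> EdgeMagnetAssignment:
    """Uniform (N, S) pole pair on every edge of every subunit.

    Realizes the self-assembly design criteria: identical subunits, full
    rotational symmetry within each subunit, and complementary (attractive)
    pole contacts across every shared edge.
    """
    poles = {
        (fi, slot): ("N", "S")
        for fi, f in enumerate(p.faces)
        for slot in range(len(f))
    }
    return EdgeMagnetAssignment(poles=dict(poles))


def enantiomer(m: EdgeMagnetAssignment) -> EdgeMagnetAssignment:
    """Globally swap every pole; the mirror-image (enantiomeric) design."""
    flip = {"N": "S", "S": "N"}
    return EdgeMagnetAssignment(
        poles={k: (flip[a], flip[b]) for k, (a, b) in m.poles.items()}
    )


def validate_magnet_map(p: Polyhedron, m: EdgeMagnetAssignment) -> MagnetReport:
    """Check a magnet assignment against the three design criteria.

    1. every subunit carries the same pattern (up to face rotation);
    2. the pattern is rotationally symmetric within each subunit;
    3. across every shared edge the pole pairs are complementary, so the
       contact attracts (N meets S twice).

    The first violating ``(face, slot)`` is reported.
    """
    # criteria 2+3 within faces: rotational symmetry means the pole pattern
    # is invariant under rotating the face, i.e. constant across slots
    patterns: list[tuple[tuple[str, str], ...]] = []
    for fi, f in enumerate(p.faces):
        seq = tuple(m.poles[(fi, slot)] for slot in range(len(f)))
        for slot in range(len(f)):
            if seq[slot] != seq[0]:
                return MagnetReport(
                    False, (fi, slot), "subunit pattern not rotationally symmetric"
                )
        patterns.append(seq)
    ref = patterns[0]
    for fi, seq in enumerate(patterns):
        if len(seq) == len(ref) and seq != ref:
            return MagnetReport(False, (fi, 0), "subunits are not identical")
    # attraction across every shared edge
    slot_of: dict[tuple[int, int, int], int] = {}
    for fi, f in enumerate(p.faces):
        for slot, (a, b) in enumerate(_cycle_pairs(f)):
            slot_of[(fi, a, b)] = slot
    for (f, g), (a, b) in p.face_adjacency:
        sf = slot_of.get((f, a, b), slot_of.get((f, b, a)))
        sg = slot_of.get((g, a, b), slot_of.get((g, b, a)))
        pf, pg = m.poles[(f, sf)], m.poles[(g, sg)]
        # the traversals run the shared edge in opposite directions, so
        # pf[0] meets pg[1] and pf[1] meets pg[0]
        if pf[0] == pg[1] or pf[1] == pg[0]:
            return MagnetReport(False, (f, sf), f"repulsive contact on edge {(a, b)}")
    return MagnetReport(True)


# ---------------------------------------------------------------------------
# Caspar-Klug triangulation number
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TNumber:
    t: int
    capsomeres: int


def triangulation_number(h: int, k: int) -> TNumber:
    """Caspar–Klug T-number ``T = h² + hk + k²`` and capsomere count 60·T.

    >>> triangulation_number(1, 1)
    TNumber(t=3, capsomeres=180)
    """
    if not (isinstance(h, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise TypeError("h and k must be integers")
    if h < 1 or k < 0:
        raise ValueError(f"require h >= 1 and k >= 0, got h={h}, k={k}")
    t = int(h * h + h * k + k * k)
    return TNumber(t=t, capsomeres=60 * t)
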