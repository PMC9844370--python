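"""Topological and geometric foldability descriptors of Dürer nets.

Seven variables measure how compact a net is and, by proxy, how well it
self-folds: vertex connections, leaves, spanning-tree length, degree
distribution, backbone (tree diameter), convex-hull area and perimeter,
and the radius of gyration.  Topological descriptors live on the
skeleton tree; geometric ones on the unit-edge planar embedding.
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .enumeration import (
    CanonicalID,
    DurerNet,
    NetCensus,
    boundary_circuit,
    canonical_id,
    net_census,
)
from .polyhedra import Polyhedron

__all__ = [
    "DegreeDistribution",
    "DescriptorRecord",
    "vertex_connections",
    "leaves",
    "skeleton_metrics",
    "degree_distribution_solutions",
    "realized_degree_distributions",
    "radius_of_gyration",
    "convex_hull_metrics",
    "describe_net",
]


@dataclass(frozen=True, order=True)
class DegreeDistribution:
    """Counts of skeleton-tree nodes by degree.

    ``counts[d-1]`` is the number of faces of skeleton degree d, so for a
    cube net the tuple (A, B, C, D) satisfies A + B + C + D = 6 and
    A + 2B + 3C + 4D = 10 (degree sum = twice the 5 tree edges).
    A is the number of leaves.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_nodes(self) -> int:
        return sum(self.counts)

    @property
    def degree_sum(self) -> int:
        return sum((d + 1) * c for d, c in enumerate(self.counts))

    @property
    def leaves(self) -> int:
        return self.counts[0] if self.counts else 0

    def padded(self, dmax: int) -> tuple[int, ...]:
        """Zero-padded count vector up to degree ``dmax`` (comparable
        across solids)."""
        return tuple(self.counts[d] if d < len(self.counts) else 0 for d in range(dmax))

    @classmethod
    def from_degrees(cls, degrees: Iterable[int], dmax: int | None = None):
        degs = list(degrees)
        top = max(degs) if dmax is None else dmax
        cnt = Counter(degs)
        return cls(counts=tuple(cnt.get(d, 0) for d in range(1, top + 1)))


@dataclass(frozen=True)
class DescriptorRecord:
    """All descriptor values for one net (one row of the study table)."""

    vertex_connections_restrictive: int
    vertex_connections_traditional: int
    leaves: int
    spanning_tree_edges: int
    degree_distribution: DegreeDistribution
    backbone_length: int
    rg: float
    rg_squared: float
    hull_area: float
    hull_perimeter: float
    canonical: CanonicalID


# ---------------------------------------------------------------------------
# Topological descriptors
# ---------------------------------------------------------------------------


def vertex_connections(
    net: DurerNet,
    definition: Literal["restrictive", "traditional"] = "restrictive",
) -> int:
    """Count vertex connections of a net under either definition.

    restrictive:
        net vertices incident in the net to *every* face they touch on
        the solid — closing the polyhedron locally needs only one edge
        gluing.  Such a vertex has net degree m + 1 where m is the number
        of faces at that solid vertex (4 for cube and dodecahedron nets,
        5 for octahedra, 6 for icosahedra); equivalently it is a leaf of
        the cutting tree.  Counted per vertex with that vertex's own m,
        so mixed-face solids are handled too.
    traditional:
        net vertices where two faces share the vertex but not an edge,
        i.e. any boundary vertex whose fan spans at least three faces
        (net degree >= 4).
    """
    if net.solid is None:
        raise ValueError("vertex connections require a net of a polyhedron")
    m = net.solid.vertex_face_count
    count = 0
    for bv in net.boundary:
        if definition == "restrictive":
            count += bv.degree == m[bv.solid_vertex] + 1
        elif definition == "traditional":
            count += bv.degree >= 4
        else:
            raise ValueError(f"unknown definition {definition!r}")
    return count


def leaves(net: DurerNet) -> int:
    """Faces sharing exactly one folded edge with the rest of the net
    (skeleton nodes of degree 1)."""
    deg = Counter()
    for a, b in net.skeleton.edges:
        deg[a] += 1
        deg[b] += 1
    return sum(1 for n in net.skeleton.nodes if deg[n] == 1)


def _tree_diameter(adjacency: dict[int, list[int]], root: int) -> int:
    """Diameter in edges via double BFS (exact on trees)."""

    def farthest(s):
        seen = {s}
        frontier = [s]
        last, dist = s, 0
        while frontier:
            nxt = []
            for u in frontier:
                for v in adjacency[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            if nxt:
                dist += 1
                last = nxt[0]
            frontier = nxt
        return last, dist

    far, _ = farthest(root)
    _, diam = farthest(far)
    return diam


def skeleton_metrics(net: DurerNet) -> dict:
    """Spanning-tree edge count, backbone length and degree distribution.

    The backbone is a longest path in the skeleton tree; several may
    exist but its length (the tree diameter, in edges) is unique.
    """
    adj = net.skeleton.adjacency
    degrees = [len(adj[n]) for n in net.skeleton.nodes]
    # pad counts up to the solid's maximal face adjacency so distributions
    # are comparable across nets and against the admissible solutions
    dmax = None
    if net.solid is not None and len(net.skeleton.nodes) == len(net.solid.faces):
        dmax = max(d for _, d in net.solid.face_graph.degree)
    dist = DegreeDistribution.from_degrees(degrees, dmax=dmax)
    return {
        "spanning_tree_edges": len(net.skeleton.edges),
        "backbone_length": _tree_diameter(adj, net.skeleton.nodes[0]),
        "degree_distribution": dist,
    }


def degree_distribution_solutions(F: int, dmax: int) -> list[DegreeDistribution]:
    """All nonnegative integer solutions of the two tree identities.

    A tree on F nodes with degrees 1..dmax satisfies
    ``sum_d n_d = F`` and ``sum_d d*n_d = 2(F - 1)``; solutions are
    returned in lexicographic order of the count vector.  Not every
    solution is realized by an actual net — which ones are is measured by
    :func:`realized_degree_distributions`.
    """
    if F < 2 or dmax < 2:
        raise ValueError("need F >= 2 and dmax >= 2")
    target_sum = 2 * (F - 1)
    sols = []

    def rec(d: int, counts: list[int], left_nodes: int, left_sum: int) -> None:
        if d == dmax:
            # final degree class must absorb exactly the remainder
            if left_sum == dmax * left_nodes:
                sols.append(DegreeDistribution(counts=tuple(counts + [left_nodes])))
            return
        for c in range(left_nodes + 1):
            rest_nodes = left_nodes - c
            rest_sum = left_sum - d * c
            if rest_sum < rest_nodes or rest_sum > rest_nodes * dmax:
                continue
            rec(d + 1, counts + [c], rest_nodes, rest_sum)

    rec(1, [], F, target_sum)
    sols.sort(key=lambda s: s.counts)
    return sols


def realized_degree_distributions(
    p: Polyhedron, census: NetCensus | None = None
) -> dict[DegreeDistribution, int]:
    """Distinct-net counts grouped by skeleton degree distribution.

    Vectorized over the census bitmasks; every realized distribution is
    one of :func:`degree_distribution_solutions` and the counts sum to
    the solid's distinct-net count.
    """
    if census is None:
        census = net_census(p)
    F = len(p.faces)
    m = len(census.edge_list)
    inc = np.zeros((m, F), np.int64)
    for i, (a, b) in enumerate(census.edge_list):
        inc[i, a] = 1
        inc[i, b] = 1
    shifts = np.arange(m, dtype=np.uint64)
    bits = (
        (census.canonical_masks[:, None] >> shifts[None, :]) & np.uint64(1)
    ).astype(np.int64)
    node_deg = bits @ inc  # (n_nets, F)
    dmax = max(d for _, d in p.face_graph.degree)
    out: dict[DegreeDistribution, int] = {}
    counts = np.stack(
        [(node_deg == d).sum(axis=1) for d in range(1, dmax + 1)], axis=1
    )
    for row, n in Counter(map(tuple, counts)).items():
        out[DegreeDistribution(counts=row)] = n
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Geometric descriptors
# ---------------------------------------------------------------------------


def radius_of_gyration(
    net: DurerNet,
    method: Literal["centroid_sum", "area_integral"] = "centroid_sum",
) -> dict[str, float]:
    """Radius of gyration of a unit-edge net.

    centroid_sum (default, the convention used for the study data):
        ``Rg² = (1/N) Σ ((xᵢ-x̄)² + (yᵢ-ȳ)²)`` over the N face centroids
        (xᵢ, yᵢ) with (x̄, ȳ) their mean — cheap, and it ranks nets nearly
        identically to the full integral.
    area_integral:
        per-unit-area second moment of the net region about its area
        centroid, ``Rg² = (1/A) ∫_Ω |r - r̄|² dA``, evaluated exactly per
        face polygon.

    Both are invariant under rigid motions and scale as Rg ∝ s under
    uniform scaling by s.
    """
    if method == "centroid_sum":
        cents = net.face_centroids
        mean = cents.mean(axis=0)
        rg2 = float(np.mean(np.sum((cents - mean) ** 2, axis=1)))
    elif method == "area_integral":
        A_tot = 0.0
        first = np.zeros(2)
        second = 0.0
        for _, poly in net.faces:
            a, c, j0 = _polygon_moments(poly)
            A_tot += a
            first += a * c
            second += j0
        centroid = first / A_tot
        # parallel axis: second moment about area centroid
        rg2 = float(second / A_tot - centroid @ centroid)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"rg": float(np.sqrt(rg2)), "rg_squared": rg2}


def _polygon_moments(poly: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Area, centroid, and polar second moment of area about the origin."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = float(cross.sum() / 2.0)
    cx = float(((x + xn) * cross).sum() / (6.0 * a))
    cy = float(((y + yn) * cross).sum() / (6.0 * a))
    ixx = float((cross * (y * y + y * yn + yn * yn)).sum() / 12.0)
    iyy = float((cross * (x * x + x * xn + xn * xn)).sum() / 12.0)
    return a, np.array([cx, cy]), ixx + iyy


def convex_hull_metrics(net: DurerNet) -> dict[str, float]:
    """Area and perimeter of the net's convex hull, in unit-edge units.

    The hull of all face-polygon vertices; its perimeter tracks round
    ("spherical") compactness while its area measures enclosed wasted
    space.
    """
    from scipy.spatial import ConvexHull, QhullError

    pts = net.all_vertices
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate (collinear) net geometry: {exc}") from exc
    # scipy 2-D convention: volume is the area, area is the perimeter
    return {"hull_area": float(hull.volume), "hull_perimeter": float(hull.area)}


def describe_net(
    p: Polyhedron, net: DurerNet, canonical: CanonicalID | None = None
) -> DescriptorRecord:
    """Assemble the full descriptor record for one net."""
    sk = skeleton_metrics(net)
    rg = radius_of_gyration(net)
    hull = convex_hull_metrics(net)
    return DescriptorRecord(
        vertex_connections_restrictive=vertex_connections(net, "restrictive"),
        vertex_connections_traditional=vertex_connections(net, "traditional"),
        leaves=leaves(net),
        spanning_tree_edges=sk["spanning_tree_edges"],
        degree_distribution=sk["degree_distribution"],
        backbone_length=sk["backbone_length"],
        rg=rg["rg"],
        rg_squared=rg["rg_squared"],
        hull_area=hull["hull_area"],
        hull_perimeter=hull["hull_perimeter"],
        canonical=canonical if canonical is not None else canonical_id(p, net),
    )
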