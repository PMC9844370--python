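"""Solid construction, symmetry groups, layouts, magnet maps, T-numbers."""
import math

import networkx as nx
import numpy as np
import pytest

import durernet as dn
from durernet.polyhedra import PolyhedronError, face_permutation


@pytest.mark.parametrize(
    "name, V, E, F",
    [
        ("tetrahedron", 4, 6, 4),
        ("cube", 8, 12, 6),
        ("octahedron", 6, 12, 8),
        ("dodecahedron", 20, 30, 12),
        ("icosahedron", 12, 30, 20),
    ],
)
def test_platonic_counts_and_unit_edges(solids, name, V, E, F):
    p = solids[name]
    assert p.vertex_count == V
    assert len(p.edges) == E
    assert len(p.faces) == F
    assert V - E + F == 2
    for a, b in p.edges:
        assert np.linalg.norm(p.vertices[a] - p.vertices[b]) == pytest.approx(
            1.0, abs=1e-9
        )


def test_unknown_solid_rejected():
    with pytest.raises(ValueError, match="unknown Platonic"):
        dn.build_platonic("rhombicosidodecahedron")


def test_inconsistent_mesh_rejected(cube):
    flipped = list(cube.faces)
    flipped[0] = flipped[0][::-1]  # reverse one face orientation
    with pytest.raises(PolyhedronError, match="traversed twice"):
        dn.Polyhedron(name="bad", vertices=cube.vertices, faces=tuple(flipped))


@pytest.mark.parametrize(
    "name, full, rot",
    [
        ("tetrahedron", 24, 12),
        ("cube", 48, 24),
        ("octahedron", 48, 24),
        ("dodecahedron", 120, 60),
        ("icosahedron", 120, 60),
    ],
)
def test_symmetry_group_orders(solids, name, full, rot):
    """Full group order is twice the rotation group for every solid."""
    p = solids[name]
    g_full = dn.symmetry_group(p, include_reflections=True)
    g_rot = dn.symmetry_group(p, include_reflections=False)
    assert g_full.order == full
    assert g_rot.order == rot == full // 2


def test_symmetry_group_structure(tetrahedron, cube):
    for p in (tetrahedron, cube):
        g = dn.symmetry_group(p)
        g.validate(p)  # identity, closure, edge/face preservation
        for perm in g:
            fp = face_permutation(p, perm)
            assert sorted(fp) == list(range(len(p.faces)))


def test_dual_face_graphs_isomorphic(solids):
    """Face-adjacency graph of a solid is the 1-skeleton of its dual."""
    pairs = [("cube", "octahedron"), ("dodecahedron", "icosahedron")]
    for a, b in pairs:
        assert nx.is_isomorphic(solids[a].face_graph, solids[b].graph)
        assert nx.is_isomorphic(solids[b].face_graph, solids[a].graph)


def _segments_cross(p1, p2, q1, q2):
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-9 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    # proper crossing: strictly opposite nonzero orientations both ways
    return o1 * o2 < 0 and o3 * o4 < 0


@pytest.mark.parametrize("name", ["cube", "dodecahedron", "icosahedron"])
def test_schlegel_layout_is_planar(solids, name):
    """Tutte embedding: straight-line drawing with no crossing edges."""
    p = solids[name]
    pos = dn.schlegel_layout(p, outer_face=0)
    assert len(pos) == p.vertex_count
    edges = list(p.edges)
    for i, (a, b) in enumerate(edges):
        for c, d in edges[i + 1 :]:
            if {a, b} & {c, d}:
                continue
            assert not _segments_cross(pos[a], pos[b], pos[c], pos[d])


def test_schlegel_bad_face_index(cube):
    with pytest.raises(IndexError):
        dn.schlegel_layout(cube, outer_face=99)


@pytest.mark.parametrize(
    "name", ["tetrahedron", "cube", "octahedron", "dodecahedron", "icosahedron"]
)
def test_magnet_map_validates_for_all_solids(solids, name):
    """A uniform complementary pole pattern self-assembles on each solid,
    and its global pole swap (the enantiomer) does too."""
    p = solids[name]
    m = dn.magnet_map(p)
    assert dn.validate_magnet_map(p, m)
    assert dn.validate_magnet_map(p, dn.enantiomer(m))


def test_magnet_map_flip_detected(cube):
    m = dn.magnet_map(cube)
    poles = dict(m.poles)
    poles[(2, 1)] = ("S", "N")  # hand-edit one pole pair
    bad = dn.EdgeMagnetAssignment(poles=poles)
    rep = dn.validate_magnet_map(cube, bad)
    assert not rep
    assert rep.violation[0] == 2


def test_magnet_map_symmetry_invariance(cube):
    """Relabeling the assignment by any symmetry still validates."""
    m = dn.magnet_map(cube)
    g = dn.symmetry_group(cube)
    perm = g.permutations[7]
    fp = face_permutation(cube, perm)
    relabeled = dn.EdgeMagnetAssignment(
        poles={(fp[f], s): pair for (f, s), pair in m.poles.items()}
    )
    assert dn.validate_magnet_map(cube, relabeled)


@pytest.mark.parametrize(
    "h, k, t, caps",
    [(1, 0, 1, 60), (1, 1, 3, 180), (2, 0, 4, 240), (3, 1, 13, 780)],
)
def test_triangulation_number(h, k, t, caps):
    res = dn.triangulation_number(h, k)
    assert (res.t, res.capsomeres) == (t, caps)


def test_triangulation_number_rejects_bad_input():
    with pytest.raises(ValueError):
        dn.triangulation_number(0, 1)
    with pytest.raises(ValueError):
        dn.triangulation_number(1, -1)
    with pytest.raises(TypeError):
        dn.triangulation_number(1.5, 0)
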