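"""Spanning-tree streams, unfolding, boundary circuits, canonical IDs."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import durernet as dn
from durernet import _treegen
from durernet.polyhedra import face_permutation


@pytest.mark.parametrize(
    "name, count", [("tetrahedron", 16), ("cube", 384), ("octahedron", 384)]
)
def test_skeleton_tree_stream_matches_kirchhoff(solids, name, count):
    """Streamed spanning trees agree exactly with the matrix-tree count."""
    p = solids[name]
    trees = list(dn.enumerate_skeleton_trees(p))
    assert len(trees) == count == dn.spanning_tree_count(p.face_graph)
    assert len({t.edges for t in trees}) == count  # emitted exactly once
    for t in trees[:50]:
        assert len(t.edges) == len(p.faces) - 1


def test_python_fallback_kernel_agrees(cube):
    """Pure-Python Gosper kernel returns the same masks as the jitted one."""
    edges = [fg for fg, _ in cube.face_adjacency]
    eu = [e[0] for e in edges]
    ev = [e[1] for e in edges]
    py = _treegen._spanning_masks_py(eu, ev, len(cube.faces))
    fast = _treegen.spanning_tree_masks(edges, len(cube.faces))
    assert np.array_equal(np.sort(py), np.sort(fast))


def test_cut_tree_complement_duality_exhaustive(cube):
    """All 384 cube skeleton trees complement to spanning, acyclic cut trees."""
    for t in dn.enumerate_skeleton_trees(cube):
        cut = dn.skeleton_to_cut_tree(cube, t)  # constructor validates
        assert len(cut.edges) == cube.vertex_count - 1
        assert len(cut.edges) == len(cube.edges) - len(t.edges)


def test_unfold_places_every_face_with_unit_edges(cube, cube_census):
    net = next(dn.enumerate_nets(cube, cube_census))
    assert net.face_count == 6
    for _, poly in net.faces:
        d = np.linalg.norm(np.roll(poly, -1, axis=0) - poly, axis=1)
        assert d == pytest.approx(np.ones(len(poly)), abs=1e-9)


def test_unfold_refolds_to_solid_adjacency(cube, cube_census):
    """Each folded hinge keeps the shared solid edge glued: the rigid
    placements of its endpoints coincide from both faces."""
    shared = {fg: e for fg, e in cube.face_adjacency}
    for net in dn.enumerate_nets(cube, cube_census):
        polys = dict(net.faces)
        for f, g in net.skeleton.edges:
            a, b = shared[(f, g)]
            for v in (a, b):
                pf = polys[f][cube.faces[f].index(v)]
                pg = polys[g][cube.faces[g].index(v)]
                assert np.linalg.norm(pf - pg) < 1e-9


def test_single_face_unfolds_to_unit_pentagon(dodecahedron):
    t = dn.SkeletonTree(nodes=(0,), edges=frozenset())
    net = dn.unfold(dodecahedron, t)
    assert net.face_count == 1
    assert dn.boundary_circuit(net) == (2, 2, 2, 2, 2)


@pytest.mark.parametrize("name, nets", [("tetrahedron", 2), ("cube", 11), ("octahedron", 11)])
def test_distinct_net_counts_small_solids(solids, name, nets):
    census = dn.net_census(solids[name])
    assert census.net_count == nets
    assert int(census.orbit_sizes.sum()) == census.tree_count


def test_orbit_sizes_divide_group_order(cube_census):
    for size in cube_census.orbit_sizes:
        assert cube_census.group_order % int(size) == 0


def test_census_cache_roundtrip(tetrahedron, tmp_path):
    path = tmp_path / "tetra.npz"
    first = dn.net_census(tetrahedron, cache_path=path)
    assert path.exists()
    second = dn.net_census(tetrahedron, cache_path=path)
    assert np.array_equal(first.canonical_masks, second.canonical_masks)
    assert np.array_equal(first.orbit_sizes, second.orbit_sizes)


def test_tetrahedron_boundary_circuits(tetrahedron):
    """Every tetrahedron net boundary has 2(V-1) = 6 stops."""
    for net in dn.enumerate_nets(tetrahedron):
        circ = dn.boundary_circuit(net)
        assert len(circ) == 6
        # degree sum: one incidence per (face, vertex) plus one per stop
        assert sum(circ) == 3 * 4 + 6


def test_all_small_solid_nets_overlap_free(solids):
    for name in ("tetrahedron", "cube", "octahedron"):
        for net in dn.enumerate_nets(solids[name]):
            assert not dn.overlap_check(net)


def test_overlapping_fan_fixture_detected():
    fan = dn.make_fixture("overlapping_fan", n=7)
    assert dn.overlap_check(fan)  # 7 * 60 degrees > 360: interiors collide


def test_fixture_parameter_validation():
    with pytest.raises(ValueError, match="n >= 7"):
        dn.make_fixture("overlapping_fan", n=6)
    with pytest.raises(ValueError, match="unknown fixture kind"):
        dn.make_fixture("moebius_net")
    with pytest.raises(ValueError, match="unknown fixture parameters"):
        dn.make_fixture("chain_net", n=4, twist=1)


def test_chain_and_star_fixtures():
    chain = dn.make_fixture("chain_net", n=6)
    assert dn.leaves(chain) == 2
    assert dn.skeleton_metrics(chain)["backbone_length"] == 5
    assert not dn.overlap_check(chain)
    star = dn.make_fixture("star_net", k=5)
    assert dn.leaves(star) == 5
    assert dn.skeleton_metrics(star)["backbone_length"] == 2
    assert not dn.overlap_check(star)


def test_canonical_id_invariant_under_symmetry_relabeling(cube, cube_census):
    """Relabeling a net by any symmetry (including mirror reflections)
    leaves both the orbit key and the degree circuit unchanged."""
    group = dn.symmetry_group(cube, include_reflections=True)
    net = next(dn.enumerate_nets(cube, cube_census))
    base = dn.canonical_id(cube, net)
    for perm in group.permutations[::5]:
        fp = face_permutation(cube, perm)
        edges = frozenset(
            tuple(sorted((fp[a], fp[b]))) for a, b in net.skeleton.edges
        )
        relabeled = dn.unfold(cube, dn.SkeletonTree(nodes=net.skeleton.nodes, edges=edges))
        other = dn.canonical_id(cube, relabeled)
        assert other == base


def test_mirror_image_net_shares_canonical_id(cube, cube_census):
    group = dn.symmetry_group(cube, include_reflections=True)
    reflection = next(
        p for p in group
        if not dn.polyhedra._preserves_orientation(p, cube)
    )
    fp = face_permutation(cube, reflection)
    for net in dn.enumerate_nets(cube, cube_census):
        edges = frozenset(tuple(sorted((fp[a], fp[b]))) for a, b in net.skeleton.edges)
        mirrored = dn.unfold(cube, dn.SkeletonTree(nodes=net.skeleton.nodes, edges=edges))
        assert dn.canonical_id(cube, mirrored) == dn.canonical_id(cube, net)


@settings(max_examples=100, deadline=None)
@given(
    seq=st.lists(st.integers(min_value=2, max_value=6), min_size=1, max_size=12),
    rot=st.integers(min_value=0, max_value=11),
    flip=st.booleans(),
)
def test_canonical_circuit_invariance(seq, rot, flip):
    """The canonical cyclic form ignores rotation and traversal direction."""
    seq = tuple(seq)
    r = rot % len(seq)
    variant = seq[r:] + seq[:r]
    if flip:
        variant = variant[::-1]
    assert dn.canonical_circuit(variant) == dn.canonical_circuit(seq)


def test_matrix_tree_count_for_user_meshes(icosahedron):
    # the count operation works on any connected graph, e.g. a path
    import networkx as nx

    assert dn.spanning_tree_count(nx.path_graph(5)) == 1
    assert dn.spanning_tree_count(nx.complete_graph(4)) == 16
    assert dn.spanning_tree_count(icosahedron.graph) == 5184000
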