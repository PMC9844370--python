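"""Foldability descriptors: vertex connections, leaves, trees, Rg, hulls."""
import dataclasses
import math
import types

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import durernet as dn
from durernet.descriptors import (
    DegreeDistribution,
    degree_distribution_solutions,
    realized_degree_distributions,
)


def _scaled(net, s):
    return dataclasses.replace(
        net,
        faces=tuple((fi, poly * s) for fi, poly in net.faces),
        net_vertex_coords={k: v * s for k, v in net.net_vertex_coords.items()},
    )


# -- skeleton-side descriptors ------------------------------------------


def test_cube_skeleton_identities(cube, cube_census):
    """Every cube net: 5 fold edges, skeleton degree sum 2e = 10."""
    for net in dn.enumerate_nets(cube, cube_census):
        sk = dn.skeleton_metrics(net)
        assert sk["spanning_tree_edges"] == 5
        assert sk["degree_distribution"].degree_sum == 10
        assert sk["degree_distribution"].n_nodes == 6


def test_cube_degree_distribution_solutions():
    """The pair of tree identities for the cube has exactly 4 solutions."""
    sols = degree_distribution_solutions(6, 4)
    assert [s.counts for s in sols] == [
        (2, 4, 0, 0),
        (3, 2, 1, 0),
        (4, 0, 2, 0),
        (4, 1, 0, 1),
    ]


def test_degree_distribution_solution_counts():
    assert len(degree_distribution_solutions(4, 3)) == 2  # tetrahedron
    assert len(degree_distribution_solutions(2, 2)) == 1  # a single edge
    assert degree_distribution_solutions(2, 2)[0].counts == (2, 0)


def test_realized_distributions_subset_of_admissible(solids):
    for name in ("tetrahedron", "cube", "octahedron"):
        p = solids[name]
        dmax = max(d for _, d in p.face_graph.degree)
        admissible = {s.counts for s in degree_distribution_solutions(len(p.faces), dmax)}
        realized = realized_degree_distributions(p)
        assert set(d.counts for d in realized) <= admissible
        census = dn.net_census(p)
        assert sum(realized.values()) == census.net_count


def test_cube_realized_distribution_counts(cube, cube_census):
    """Per-distribution net counts 4, 5, 1, 1 summing to the 11 cube nets."""
    realized = realized_degree_distributions(cube, cube_census)
    assert {d.counts: n for d, n in realized.items()} == {
        (2, 4, 0, 0): 4,
        (3, 2, 1, 0): 5,
        (4, 0, 2, 0): 1,
        (4, 1, 0, 1): 1,
    }


def test_leaves_equal_degree_one_count(cube, octahedron):
    """leaves(net) always matches A of the degree distribution."""
    for p in (cube, octahedron):
        for net in dn.enumerate_nets(p):
            sk = dn.skeleton_metrics(net)
            assert dn.leaves(net) == sk["degree_distribution"].leaves


def test_vertex_connection_definitions_ordered(octa_nets):
    """The traditional definition admits every restrictive vertex
    connection plus wider-angle contacts, so it can only count more."""
    for net in octa_nets:
        r = dn.vertex_connections(net, "restrictive")
        t = dn.vertex_connections(net, "traditional")
        assert t >= r


def test_single_face_has_no_vertex_connections(dodecahedron):
    net = dn.unfold(dodecahedron, dn.SkeletonTree(nodes=(0,), edges=frozenset()))
    assert dn.vertex_connections(net, "restrictive") == 0
    assert dn.vertex_connections(net, "traditional") == 0
    assert dn.leaves(net) == 0


def test_icosahedron_circuit_characterizations(icosahedron, icosa_census):
    """On icosahedron nets the restrictive vertex connections are exactly
    the degree-6 boundary stops, and the leaves are exactly the faces
    owning a degree-2 boundary vertex."""
    masks = icosa_census.canonical_masks[:: len(icosa_census.canonical_masks) // 60]
    for mask in masks:
        net = dn.unfold(icosahedron, icosa_census.skeleton_tree(int(mask)))
        circ = dn.boundary_circuit(net)
        assert len(circ) == 22
        assert dn.vertex_connections(net, "restrictive") == circ.count(6)
        # faces owning a degree-2 net vertex are exactly the leaves
        deg2_coords = [
            net.net_vertex_coords[bv.net_vertex]
            for bv in net.boundary
            if bv.degree == 2
        ]
        owners = {
            fi
            for fi, poly in net.faces
            for pt in poly
            if any(np.linalg.norm(pt - c) < 1e-9 for c in deg2_coords)
        }
        assert dn.leaves(net) == len(owners)


# -- geometric descriptors ----------------------------------------------


def test_two_triangle_rg_matches_closed_form(icosahedron):
    """Two unit triangles sharing an edge: centroids sit sqrt(3)/6 from
    the shared edge on either side, so Rg^2 = (1/sqrt(12))^2 = 1/12."""
    f, g = next(iter(icosahedron.face_graph.edges))
    t = dn.SkeletonTree(nodes=(f, g), edges=frozenset([(f, g)]))
    net = dn.unfold(icosahedron, t)
    rg = dn.radius_of_gyration(net, "centroid_sum")
    assert rg["rg_squared"] == pytest.approx(1.0 / 12.0, abs=1e-12)
    assert rg["rg"] == pytest.approx(math.sqrt(1.0 / 12.0), abs=1e-12)


def test_area_integral_rg_unit_square(cube):
    """A single unit square about its center: (1/A)∫r²dA = 1/6."""
    net = dn.unfold(cube, dn.SkeletonTree(nodes=(0,), edges=frozenset()))
    rg = dn.radius_of_gyration(net, "area_integral")
    assert rg["rg_squared"] == pytest.approx(1.0 / 6.0, abs=1e-12)


def test_centroid_sum_matches_brute_force_oracle(cube_nets, octa_nets):
    """Rg from the implementation equals an explicit centroid-list,
    explicit-mean computation."""
    for net in cube_nets + octa_nets:
        cents = [poly.mean(axis=0) for _, poly in net.faces]
        mx = sum(c[0] for c in cents) / len(cents)
        my = sum(c[1] for c in cents) / len(cents)
        oracle = sum((c[0] - mx) ** 2 + (c[1] - my) ** 2 for c in cents) / len(cents)
        assert dn.radius_of_gyration(net)["rg_squared"] == pytest.approx(
            oracle, rel=1e-12
        )


@settings(max_examples=25, deadline=None)
@given(s=st.floats(min_value=0.05, max_value=20.0, allow_nan=False))
def test_rg_scales_linearly(cube_nets, s):
    """Homogeneity: scaling a net by s scales Rg by s and Rg^2 by s^2."""
    net = cube_nets[0]
    base = dn.radius_of_gyration(net)
    scaled = dn.radius_of_gyration(_scaled(net, s))
    assert scaled["rg"] == pytest.approx(base["rg"] * s, rel=1e-9)
    assert scaled["rg_squared"] == pytest.approx(base["rg_squared"] * s * s, rel=1e-9)


def test_rg_rigid_motion_invariance(cube_nets):
    net = cube_nets[2]
    theta = 0.7
    R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    shift = np.array([3.5, -1.25])
    moved = dataclasses.replace(
        net,
        faces=tuple((fi, poly @ R.T + shift) for fi, poly in net.faces),
        net_vertex_coords={k: R @ v + shift for k, v in net.net_vertex_coords.items()},
    )
    for method in ("centroid_sum", "area_integral"):
        a = dn.radius_of_gyration(net, method)["rg"]
        b = dn.radius_of_gyration(moved, method)["rg"]
        assert b == pytest.approx(a, abs=1e-9)
    ha = dn.convex_hull_metrics(net)
    hb = dn.convex_hull_metrics(moved)
    assert hb["hull_area"] == pytest.approx(ha["hull_area"], abs=1e-9)
    assert hb["hull_perimeter"] == pytest.approx(ha["hull_perimeter"], abs=1e-9)


def test_pentagon_hull_closed_forms(dodecahedron):
    net = dn.unfold(dodecahedron, dn.SkeletonTree(nodes=(0,), edges=frozenset()))
    hull = dn.convex_hull_metrics(net)
    assert hull["hull_perimeter"] == pytest.approx(5.0, abs=1e-9)
    assert hull["hull_area"] == pytest.approx(
        0.25 * math.sqrt(5 * (5 + 2 * math.sqrt(5))), abs=1e-9
    )


def test_hull_area_bounds_total_face_area(octa_nets):
    tri_area = math.sqrt(3) / 4
    for net in octa_nets:
        hull = dn.convex_hull_metrics(net)
        assert hull["hull_area"] >= 8 * tri_area - 1e-9


def test_degenerate_hull_rejected():
    fake = types.SimpleNamespace(
        all_vertices=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    )
    with pytest.raises(ValueError, match="degenerate"):
        dn.convex_hull_metrics(fake)


def test_describe_net_record_consistency(cube, cube_census):
    for net in dn.enumerate_nets(cube, cube_census):
        rec = dn.describe_net(cube, net)
        assert rec.spanning_tree_edges == 5
        assert rec.leaves == rec.degree_distribution.leaves
        assert rec.rg_squared == pytest.approx(rec.rg**2, rel=1e-12)
        assert rec.hull_area >= 6.0 - 1e-9  # hull contains the six unit squares
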