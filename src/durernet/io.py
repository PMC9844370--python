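"""Mesh interchange (ASCII OFF / OBJ) and SVG rendering.

OFF is the interchange format: plain vertex and face lists, no
triangulation, so polygonal (e.g. pentagonal) faces survive a roundtrip
exactly.  OBJ is accepted read-only as a courtesy dialect.  SVG output
is deliberately minimal: one polygon element per face at unit-edge
scale, with optional overlays for the skeleton tree, backbone, vertex
connections and leaves.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np

from .descriptors import leaves as _leaf_count  # noqa: F401 (re-export context)
from .enumeration import DurerNet
from .polyhedra import Polyhedron

__all__ = [
    "OffFormatError",
    "read_off",
    "write_off",
    "read_obj",
    "render_net_svg",
    "render_schlegel_svg",
]

#: significant digits for serialized coordinates
FLOAT_DIGITS = 12


class OffFormatError(ValueError):
    """Malformed OFF/OBJ input; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _fmt(x: float) -> str:
    return f"{x:.{FLOAT_DIGITS}g}"


def read_off(path: str | Path, name: str | None = None) -> Polyhedron:
    """Read an ASCII OFF mesh as a unit-edge polyhedron.

    Header line ``OFF``, then ``V F E`` counts, V coordinate lines, F
    face lines (``k i1 .. ik``).  The mesh must satisfy the closed-
    surface invariants (Euler characteristic 2, unit edges, two faces
    per edge).
    """
    path = Path(path)
    lines = []
    for no, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.split("#", 1)[0].strip()
        if text:
            lines.append((no, text))
    if not lines:
        raise OffFormatError(path, 1, "empty file")
    pos = 0
    if lines[0][1].upper() == "OFF":
        pos = 1
    elif lines[0][1].upper().startswith("OFF"):  # counts on the header line
        lines[0] = (lines[0][0], lines[0][1][3:].strip())
    no, counts = lines[pos]
    parts = counts.split()
    if len(parts) < 3:
        raise OffFormatError(path, no, f"expected 'V F E' counts, got {counts!r}")
    try:
        nv, nf = int(parts[0]), int(parts[1])
    except ValueError:
        raise OffFormatError(path, no, f"non-integer counts {counts!r}") from None
    pos += 1
    if len(lines) < pos + nv + nf:
        raise OffFormatError(path, lines[-1][0], "truncated file")
    verts = []
    for no, text in lines[pos : pos + nv]:
        parts = text.split()
        if len(parts) < 3:
            raise OffFormatError(path, no, f"expected 3 coordinates, got {text!r}")
        try:
            verts.append([float(v) for v in parts[:3]])
        except ValueError:
            raise OffFormatError(path, no, f"bad coordinate in {text!r}") from None
    faces = []
    for no, text in lines[pos + nv : pos + nv + nf]:
        parts = text.split()
        try:
            k = int(parts[0])
            idx = [int(v) for v in parts[1 : 1 + k]]
        except (ValueError, IndexError):
            raise OffFormatError(path, no, f"bad face line {text!r}") from None
        if len(idx) != k:
            raise OffFormatError(path, no, f"face promises {k} vertices, lists {len(idx)}")
        for v in idx:
            if not 0 <= v < nv:
                raise OffFormatError(path, no, f"face references missing vertex {v}")
        faces.append(tuple(idx))
    return Polyhedron(
        name=name or path.stem, vertices=np.asarray(verts), faces=tuple(faces)
    )


def write_off(p: Polyhedron, path: str | Path) -> None:
    """Write an ASCII OFF file (roundtrips combinatorics and coordinates)."""
    path = Path(path)
    out = ["OFF", f"{p.vertex_count} {len(p.faces)} {len(p.edges)}"]
    for v in p.vertices:
        out.append(" ".join(_fmt(x) for x in v))
    for f in p.faces:
        out.append(f"{len(f)} " + " ".join(map(str, f)))
    path.write_text("\n".join(out) + "\n")


def read_obj(path: str | Path, name: str | None = None) -> Polyhedron:
    """Read a Wavefront OBJ mesh (``v``/``f`` records only), courtesy dialect."""
    path = Path(path)
    verts, faces = [], []
    for no, raw in enumerate(path.read_text().splitlines(), start=1):
        parts = raw.split("#", 1)[0].split()
        if not parts:
            continue
        if parts[0] == "v":
            try:
                verts.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise OffFormatError(path, no, f"bad vertex {raw!r}") from None
        elif parts[0] == "f":
            try:
                faces.append(
                    tuple(int(tok.split("/", 1)[0]) - 1 for tok in parts[1:])
                )
            except ValueError:
                raise OffFormatError(path, no, f"bad face {raw!r}") from None
    if not verts or not faces:
        raise OffFormatError(path, 1, "no v/f records found")
    return Polyhedron(name=name or path.stem, vertices=np.asarray(verts), faces=tuple(faces))


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_SVG_HEAD = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<svg xmlns="http://www.w3.org/2000/svg" viewBox="{vb}" width="{w}" height="{h}">\n'
)


def _svg_points(poly: np.ndarray) -> str:
    return " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in poly)


def render_net_svg(
    net: DurerNet,
    path: str | Path,
    overlays: Iterable[str] = (),
    scale: float = 40.0,
) -> None:
    """Render a net as SVG: one polygon per face at unit-edge scale.

    Overlays: ``"skeleton"`` (fold-hinge tree through face centroids),
    ``"backbone"`` (a longest skeleton path), ``"vertex_connections"``
    (markers on restrictive vertex connections), ``"leaves"`` (shade
    faces of skeleton degree 1).
    """
    overlays = set(overlays)
    unknown = overlays - {"skeleton", "backbone", "vertex_connections", "leaves"}
    if unknown:
        raise ValueError(f"unknown overlays: {sorted(unknown)}")
    pts = net.all_vertices
    lo = pts.min(axis=0) - 0.6
    hi = pts.max(axis=0) + 0.6
    span = hi - lo
    vb = f"{_fmt(lo[0])} {_fmt(lo[1])} {_fmt(span[0])} {_fmt(span[1])}"
    parts = [
        _SVG_HEAD.format(vb=vb, w=_fmt(span[0] * scale), h=_fmt(span[1] * scale))
    ]
    leafy = set()
    if "leaves" in overlays:
        adj = net.skeleton.adjacency
        leafy = {n for n in net.skeleton.nodes if len(adj[n]) == 1}
    for fi, poly in net.faces:
        fill = "#f4c97a" if fi in leafy else "#9fc5e8"
        parts.append(
            f'  <polygon points="{_svg_points(poly)}" fill="{fill}" '
            'stroke="black" stroke-width="0.03"/>\n'
        )
    cent = {fi: poly.mean(axis=0) for fi, poly in net.faces}
    if "skeleton" in overlays or "backbone" in overlays:
        for a, b in sorted(net.skeleton.edges):
            parts.append(
                f'  <line x1="{_fmt(cent[a][0])}" y1="{_fmt(cent[a][1])}" '
                f'x2="{_fmt(cent[b][0])}" y2="{_fmt(cent[b][1])}" '
                'stroke="#333333" stroke-width="0.05"/>\n'
            )
    if "backbone" in overlays:
        import networkx as nx

        g = nx.Graph(list(net.skeleton.edges))
        g.add_nodes_from(net.skeleton.nodes)
        ecc = nx.eccentricity(g)
        a = min(ecc, key=lambda n: (-ecc[n], n))
        lengths, paths = nx.single_source_dijkstra(g, a)
        b = min(lengths, key=lambda n: (-lengths[n], n))
        bp = paths[b]
        for u, v in zip(bp, bp[1:]):
            parts.append(
                f'  <line x1="{_fmt(cent[u][0])}" y1="{_fmt(cent[u][1])}" '
                f'x2="{_fmt(cent[v][0])}" y2="{_fmt(cent[v][1])}" '
                'stroke="#1155cc" stroke-width="0.09"/>\n'
            )
    if "vertex_connections" in overlays and net.solid is not None:
        m = net.solid.vertex_face_count
        for bv in net.boundary:
            if bv.degree == m[bv.solid_vertex] + 1:
                x, y = net.net_vertex_coords[bv.net_vertex]
                parts.append(
                    f'  <circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="0.12" '
                    'fill="#cc0000"/>\n'
                )
    parts.append("</svg>\n")
    Path(path).write_text("".join(parts))


def render_schlegel_svg(
    p: Polyhedron, path: str | Path, outer_face: int = 0, scale: float = 200.0
) -> None:
    """Render the Schlegel (Tutte) layout of a polyhedron's 1-skeleton."""
    from .polyhedra import schlegel_layout

    pos = schlegel_layout(p, outer_face)
    arr = np.stack([pos[v] for v in sorted(pos)])
    lo, hi = arr.min(axis=0) - 0.2, arr.max(axis=0) + 0.2
    span = hi - lo
    vb = f"{_fmt(lo[0])} {_fmt(lo[1])} {_fmt(span[0])} {_fmt(span[1])}"
    parts = [
        _SVG_HEAD.format(vb=vb, w=_fmt(span[0] * scale), h=_fmt(span[1] * scale))
    ]
    for a, b in p.edges:
        parts.append(
            f'  <line x1="{_fmt(pos[a][0])}" y1="{_fmt(pos[a][1])}" '
            f'x2="{_fmt(pos[b][0])}" y2="{_fmt(pos[b][1])}" '
            'stroke="black" stroke-width="0.01"/>\n'
        )
    for v in sorted(pos):
        parts.append(
            f'  <circle cx="{_fmt(pos[v][0])}" cy="{_fmt(pos[v][1])}" r="0.03" '
            'fill="#cc0000"/>\n'
        )
    parts.append("</svg>\n")
    Path(path).write_text("".join(parts))
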