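"""Study-level assembly: descriptor tables, correlations, sampling, reports.

This is the stage that turns the exhaustive enumeration into the
comparative results: one descriptor row per distinct net, the
compactness correlations (convex-hull perimeter and area against the
radius of gyration), and the stratified sampling scheme used to pick
folding candidates spanning all vertex-connection categories.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import (
    DegreeDistribution,
    degree_distribution_solutions,
    describe_net,
    realized_degree_distributions,
)
from .enumeration import (
    CanonicalID,
    NetCensus,
    boundary_circuit,
    canonical_circuit,
    net_census,
    unfold,
)
from .polyhedra import Polyhedron

__all__ = [
    "CorrelationResult",
    "SampleDesign",
    "descriptor_table",
    "correlate",
    "stratified_sample",
    "stratum_correlations",
    "summary_report",
    "format_report",
]

#: stable column order of the descriptor table (documented interface)
TABLE_COLUMNS = (
    "orbit_key",
    "degree_circuit",
    "vertex_connections",
    "vertex_connections_traditional",
    "leaves",
    "spanning_tree_edges",
    "backbone_length",
    "degree_distribution",
    "rg",
    "rg_squared",
    "hull_area",
    "hull_perimeter",
    "orbit_size",
)


@dataclass(frozen=True)
class CorrelationResult:
    """Simple linear association between two descriptor columns.

    ``r_squared`` is the squared Pearson correlation, which equals the
    OLS coefficient of determination for simple regression in either
    orientation, hence symmetric in x and y.
    """

    x_label: str
    y_label: str
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass(frozen=True)
class SampleDesign:
    """Stratified selection plan for folding experiments.

    Nets are grouped by ``stratum`` (e.g. vertex connections) and within
    each stratum ``k`` nets are picked spanning the ``spread`` key: for
    k = 3 the minimum, the closest to the median, and the maximum — so
    every category is represented with deliberately different geometry.
    """

    stratum: str = "vertex_connections"
    k: int = 3
    spread: str = "hull_perimeter"
    seed: int = 0
    strata: tuple | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def descriptor_table(
    p: Polyhedron,
    census: NetCensus | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """One row of descriptor values per distinct net of the solid.

    Row order follows the canonical skeleton bitmasks of the census, so
    the table is byte-stable across runs.  The orbit key reuses the
    census's canonical mask (already the minimal image over the full
    symmetry group) instead of re-minimizing per net.
    """
    if census is None:
        census = net_census(p)
    rows = []
    iterator = enumerate(census.canonical_masks)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(iterator, total=census.net_count)  # pragma: no cover
    for i, mask in iterator:
        tree = census.skeleton_tree(int(mask))
        net = unfold(p, tree)
        canonical = CanonicalID(
            orbit_key=tuple(sorted(tree.edges)),
            degree_circuit=canonical_circuit(boundary_circuit(net)),
        )
        rec = describe_net(p, net, canonical=canonical)
        rows.append(
            (
                ";".join(f"{a}-{b}" for a, b in canonical.orbit_key),
                "-".join(map(str, canonical.degree_circuit)),
                rec.vertex_connections_restrictive,
                rec.vertex_connections_traditional,
                rec.leaves,
                rec.spanning_tree_edges,
                rec.backbone_length,
                ",".join(map(str, rec.degree_distribution.counts)),
                rec.rg,
                rec.rg_squared,
                rec.hull_area,
                rec.hull_perimeter,
                int(census.orbit_sizes[i]),
            )
        )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def correlate(
    xs: Sequence[float],
    ys: Sequence[float],
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Squared Pearson correlation with the least-squares line.

    >>> correlate([0, 1, 2], [1, 3, 5]).r_squared
    1.0
    """
    from scipy import stats

    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(xs) < 3:
        raise ValueError("need at least 3 points to correlate")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        zero = x_label if np.ptp(xs) == 0 else y_label
        raise ValueError(f"zero variance in {zero!r}: correlation undefined")
    res = stats.linregress(xs, ys)
    return CorrelationResult(
        x_label=x_label,
        y_label=y_label,
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n=len(xs),
    )


def stratified_sample(table: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Deterministic stratified selection of nets from a descriptor table.

    Within each stratum the rows are ordered by the spread key (ties
    broken by a seed-fixed shuffle, so equal-spread rows are chosen
    reproducibly) and k evenly spaced order statistics are taken: k = 1
    gives the stratum minimum, k = 3 gives minimum / closest-to-median /
    maximum.  Requested strata with no rows are reported and skipped.
    """
    for col in (design.stratum, design.spread):
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    rng = np.random.default_rng(design.seed)
    present = sorted(table[design.stratum].unique())
    strata = list(design.strata) if design.strata is not None else present
    picks = []
    skipped = []
    for s in strata:
        sub = table[table[design.stratum] == s]
        if sub.empty:
            skipped.append(s)
            continue
        order = rng.permutation(len(sub))
        sub = sub.iloc[order].sort_values(design.spread, kind="stable")
        n = len(sub)
        if design.k == 1:
            idx = [0]
        else:
            idx = sorted(
                {round(i * (n - 1) / (design.k - 1)) for i in range(design.k)}
            )
        picks.append(sub.iloc[idx])
    out = (
        pd.concat(picks).reset_index(drop=True)
        if picks
        else table.iloc[:0].copy()
    )
    out.attrs["skipped_strata"] = skipped
    out.attrs["design"] = design
    return out


def stratum_correlations(
    table: pd.DataFrame,
    stratum: str = "vertex_connections",
    x: str = "hull_perimeter",
    y: str = "rg",
) -> dict:
    """Per-stratum Pearson association of two descriptor columns.

    Used to check that the perimeter–Rg relation holds inside every
    vertex-connection category, not just pooled.
    """
    out = {}
    for s in sorted(table[stratum].unique()):
        sub = table[table[stratum] == s]
        if len(sub) < 3 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
            continue
        out[int(s)] = correlate(sub[x], sub[y], x, y)
    return out


def summary_report(
    p: Polyhedron,
    table: pd.DataFrame | None = None,
    census: NetCensus | None = None,
) -> dict:
    """Machine-readable summary for one solid.

    Contains the distinct-net and spanning-tree counts, the admissible
    and realized degree distributions with per-distribution net counts,
    and — when the descriptor table is supplied and complete — the
    hull-perimeter/Rg and hull-area/Rg correlations.  Incomplete inputs
    mark their sections ``"incomplete"`` instead of reporting numbers.
    """
    if census is None:
        census = net_census(p)
    F = len(p.faces)
    dmax = max(dict(p.face_graph.degree).values())
    realized = realized_degree_distributions(p, census)
    report = {
        "solid": p.name,
        "faces": F,
        "net_count": census.net_count,
        "spanning_tree_count": census.tree_count,
        "symmetry_group_order": census.group_order,
        "degree_distributions": {
            "admissible": [list(d.counts) for d in degree_distribution_solutions(F, dmax)],
            "realized": [
                {"counts": list(d.counts), "nets": n} for d, n in realized.items()
            ],
            "n_realized": len(realized),
        },
    }
    if table is None:
        report["correlations"] = "incomplete"
    elif len(table) != census.net_count:
        report["correlations"] = "incomplete"
    else:
        pr = correlate(table["hull_perimeter"], table["rg"], "hull_perimeter", "rg")
        ar = correlate(table["hull_area"], table["rg"], "hull_area", "rg")
        report["correlations"] = {
            "hull_perimeter_vs_rg": {"r_squared": pr.r_squared, "p_value": pr.p_value, "n": pr.n},
            "hull_area_vs_rg": {"r_squared": ar.r_squared, "p_value": ar.p_value, "n": ar.n},
        }
    return report


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`summary_report` output."""
    lines = [
        f"solid: {report['solid']} ({report['faces']} faces)",
        f"distinct nets: {report['net_count']:,} "
        f"(from {report['spanning_tree_count']:,} spanning trees, "
        f"symmetry group order {report['symmetry_group_order']})",
        "degree distributions (counts by node degree 1..dmax):",
    ]
    dd = report["degree_distributions"]
    realized = {tuple(r["counts"]): r["nets"] for r in dd["realized"]}
    for counts in dd["admissible"]:
        n = realized.get(tuple(counts))
        tag = f"{n} nets" if n is not None else "not realized"
        lines.append(f"  {tuple(counts)}: {tag}")
    lines.append(f"realized distributions: {dd['n_realized']}")
    corr = report["correlations"]
    if corr == "incomplete":
        lines.append("correlations: incomplete (full descriptor table required)")
    else:
        for k, v in corr.items():
            lines.append(f"R^2({k}) = {v['r_squared']:.3f}  (n = {v['n']:,})")
    return "\n".join(lines)
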