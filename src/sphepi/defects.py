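"""Topological defect analysis of spherical packings.

Each cell of a triangulated sphere carries a topological charge
``q = 6 - valence`` (+1 pentagon, -1 heptagon).  By Euler's theorem the
charges on any sphere-topology triangulation sum to +12.  The defectiveness
statistic is the total negative charge

    Q_minus = sum_{i >= 7} N_i * (i - 6),

zero for the most regular packings (exactly twelve 5-valent cells), and the
relative defectiveness is Q_minus / N.  Charged cells that touch each other
form extended topological defects (ETDs): linear alternating 5/7 chains are
scars (net charge +1) or pleats (net charge 0, topologically a dislocation),
while branched or strongly charged aggregates are complex ETDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DefectClass",
    "ChargeAssignment",
    "DefectCluster",
    "DefectSummary",
    "topological_charges",
    "q_minus",
    "relative_defectiveness",
    "find_defect_clusters",
    "classify_cluster",
    "etd_rotation_angle",
    "analyze_defects",
    "defect_report",
    "write_defect_report",
]


class DefectClass(str, Enum):
    """Classification of a connected cluster of charged cells."""

    ISOLATED_5 = "isolated_5_disclination"
    ISOLATED_7 = "isolated_7_disclination"
    DISLOCATION = "dislocation"
    PLEAT = "pleat"
    SIMPLEST_SCAR = "simplest_scar"
    SCAR = "scar"
    COMPLEX = "complex_ETD"


@dataclass(frozen=True)
class ChargeAssignment:
    """Per-vertex topological charges q = 6 - valence."""

    charges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.charges.sum())


def topological_charges(valences: np.ndarray) -> ChargeAssignment:
    """Topological charge of every vertex: 6 minus its neighbor count."""
    return ChargeAssignment(charges=6 - np.asarray(valences, dtype=int))


def q_minus(histogram: dict[int, int]) -> int:
    """Total negative topological charge magnitude, sum_{i>=7} N_i (i-6)."""
    return int(sum(count * (i - 6) for i, count in histogram.items() if i >= 7))


def relative_defectiveness(q: float, n_cells: float) -> float:
    """Relative defectiveness Q_minus / N."""
    if n_cells <= 0:
        raise ValueError(f"n_cells must be positive, got {n_cells}")
    return q / n_cells


@dataclass
class DefectCluster:
    """Connected set of charged vertices with its net charge and class label."""

    vertices: tuple[int, ...]
    charge: int
    label: DefectClass | None = None


def find_defect_clusters(tri, charges: ChargeAssignment | np.ndarray) -> list[DefectCluster]:
    """Connected components of the subgraph induced by charged vertices.

    Connectivity is Delaunay adjacency restricted to charged vertices; every
    charged vertex belongs to exactly one cluster.  ``tri`` needs only an
    ``adjacency`` attribute (vertex -> neighbor set).
    """
    q = charges.charges if isinstance(charges, ChargeAssignment) else np.asarray(charges, int)
    charged = {v for v in range(len(q)) if q[v] != 0}
    graph = nx.Graph()
    graph.add_nodes_from(charged)
    for v in charged:
        for w in tri.adjacency[v]:
            if w in charged:
                graph.add_edge(v, w)
    clusters = []
    for comp in nx.connected_components(graph):
        verts = tuple(sorted(int(v) for v in comp))
        clusters.append(DefectCluster(vertices=verts, charge=int(sum(q[v] for v in verts))))
    return sorted(clusters, key=lambda c: c.vertices)


def _is_alternating_path(vertices: tuple[int, ...], adj) -> tuple[bool, bool]:
    """(is simple path, alternates between valence 5 and 7 along it)."""
    vset = set(vertices)
    deg = {v: len(adj[v] & vset) for v in vertices}
    if len(vertices) == 1:
        return True, True
    ends = [v for v in vertices if deg[v] == 1]
    if any(d > 2 for d in deg.values()) or len(ends) != 2:
        return False, False
    # walk the path from one endpoint
    order = [ends[0]]
    prev = None
    while len(order) < len(vertices):
        nxt = [w for w in adj[order[-1]] & vset if w != prev]
        if len(nxt) != 1:
            return False, False  # cycle or branch
        prev = order[-1]
        order.append(nxt[0])
    vals = [len(adj[v]) for v in order]
    alternating = all({vals[i], vals[i + 1]} == {5, 7} for i in range(len(vals) - 1))
    return True, alternating


def classify_cluster(cluster: DefectCluster, tri) -> DefectClass:
    """Assign exactly one class label to a defect cluster.

    Singleton +1/-1 charges are point disclinations; an adjacent 5-7 pair is
    a dislocation; strictly alternating 5/7 simple paths are pleats (equal
    counts, net charge 0) or scars (one extra 5, net charge +1; the 5-7-5
    triple is the simplest scar).  Anything branched, containing a vertex of
    valence >= 8, or with |net charge| > 1 is a complex ETD.
    """
    if not cluster.vertices:
        raise ValueError("cannot classify an empty cluster")
    adj = tri.adjacency
    vals = [len(adj[v]) for v in cluster.vertices]
    z = cluster.charge
    if any(v >= 8 for v in vals):
        return DefectClass.COMPLEX
    if len(cluster.vertices) == 1:
        if z == 1:
            return DefectClass.ISOLATED_5
        if z == -1:
            return DefectClass.ISOLATED_7
        return DefectClass.COMPLEX
    if len(cluster.vertices) == 2 and sorted(vals) == [5, 7]:
        return DefectClass.DISLOCATION
    is_path, alternating = _is_alternating_path(cluster.vertices, adj)
    if not (is_path and alternating):
        return DefectClass.COMPLEX
    if z == 0:
        return DefectClass.PLEAT
    if z == 1:
        return DefectClass.SIMPLEST_SCAR if len(cluster.vertices) == 3 else DefectClass.SCAR
    return DefectClass.COMPLEX


def etd_rotation_angle(z: int) -> float:
    """Rotation of the hexagonal-order translation circulated around an ETD
    of topological charge Z: pi * Z / 3 radians."""
    return np.pi * z / 3.0


@dataclass
class DefectSummary:
    """Full defect inventory of a triangulated spherical packing."""

    histogram: dict[int, int]
    q_minus: int
    relative: float
    clusters: list[DefectCluster] = field(default_factory=list)
    total_charge: int = 12

    @property
    def n_cells(self) -> int:
        return sum(self.histogram.values())


def analyze_defects(tri) -> DefectSummary:
    """Valence histogram, Q_minus, Q_minus/N and classified defect clusters."""
    from .tessellation import valence_histogram, valences

    vals = valences(tri)
    charges = topological_charges(vals)
    hist = valence_histogram(vals)
    clusters = find_defect_clusters(tri, charges)
    for c in clusters:
        c.label = classify_cluster(c, tri)
    q = q_minus(hist)
    return DefectSummary(
        histogram=hist, q_minus=q,
        relative=relative_defectiveness(q, len(vals)),
        clusters=clusters, total_charge=charges.total,
    )


def defect_report(summary: DefectSummary) -> dict:
    """JSON-serializable defect report."""
    return {
        "n_cells": summary.n_cells,
        "valence_histogram": {str(k): int(v) for k, v in summary.histogram.items()},
        "q_minus": summary.q_minus,
        "relative_defectiveness": summary.relative,
        "total_charge": summary.total_charge,
        "clusters": [
            {"vertices": list(c.vertices), "charge": c.charge,
             "label": c.label.value if c.label else None}
            for c in summary.clusters
        ],
    }


def write_defect_report(summary: DefectSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(defect_report(summary), indent=2) + "\n")
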