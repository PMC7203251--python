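"""Spherical Delaunay triangulation and Voronoi tessellation.

For points on a sphere the Delaunay triangulation coincides with the convex
hull of the point set, so the triangulation is obtained from Qhull
(``scipy.spatial.ConvexHull``) with triangulated output, which resolves
cocircular ties deterministically for a fixed input order.  Near-degenerate
quadruples ("square order" regions, where four cells share a contact and the
triangulation is ambiguous) are detected and reported rather than hidden.

The Voronoi diagram is the spherical dual (``scipy.spatial.SphericalVoronoi``);
each cell's edge count equals its site's Delaunay valence.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError, SphericalVoronoi

from .packing import DegenerateGeometryError

__all__ = [
    "SphericalTriangulation",
    "VoronoiCells",
    "delaunay_on_sphere",
    "voronoi_on_sphere",
    "valences",
    "valence_histogram",
    "write_off",
    "write_ply",
    "write_valence_histogram",
]

#: Coplanarity slack below which a quadrilateral of adjacent triangles is
#: flagged as an ambiguous (near-cocircular) "square order" region.
DEGENERACY_SLACK = 1e-9


@dataclass
class SphericalTriangulation:
    """Delaunay triangle mesh on the sphere.

    ``faces`` are outward-oriented vertex triples indexing ``points``;
    ``adjacency`` maps each vertex to its neighbor set.  ``ambiguous_quads``
    lists near-cocircular quadruples (sorted vertex tuples) whose diagonal
    choice is a tie-break, mirroring square-order regions in real monolayers.
    """

    points: np.ndarray
    faces: np.ndarray
    adjacency: list[set[int]] = field(repr=False, default=None)
    ambiguous_quads: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.adjacency is None:
            adj = [set() for _ in range(len(self.points))]
            for a, b, c in self.faces:
                adj[a].update((b, c))
                adj[b].update((a, c))
                adj[c].update((a, b))
            self.adjacency = adj

    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency) // 2

    def edges(self) -> set[tuple[int, int]]:
        return {(v, w) for v, nb in enumerate(self.adjacency) for w in nb if v < w}

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def face_circumcenters(self) -> np.ndarray:
        """Unit circumcenter of each face, on the same side of the sphere as
        the face (these are the spherical Voronoi vertices)."""
        a = self.points[self.faces[:, 0]]
        b = self.points[self.faces[:, 1]]
        c = self.points[self.faces[:, 2]]
        n = np.cross(b - a, c - a)
        n /= np.linalg.norm(n, axis=1)[:, None]
        # outward-oriented faces put the circumcenter along +n
        return n


def _orient_outward(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip faces so that (a, b, c) is counter-clockwise seen from outside
    (triple product with the face centroid positive)."""
    a = points[faces[:, 0]]
    b = points[faces[:, 1]]
    c = points[faces[:, 2]]
    det = np.einsum("ij,ij->i", np.cross(b - a, c - a), (a + b + c) / 3.0)
    flipped = faces.copy()
    flip = det < 0
    flipped[flip, 1], flipped[flip, 2] = faces[flip, 2], faces[flip, 1]
    return flipped


def _near_degenerate_quads(points: np.ndarray, faces: np.ndarray) -> list[tuple]:
    """Quadruples of nearly cocircular vertices across each interior edge.

    Four points on the sphere are cocircular iff coplanar; the slack is the
    distance of the fourth point from the plane of the other three.
    """
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(u, v), max(u, v)), []).append(fi)
    quads = set()
    for (u, v), fids in edge_faces.items():
        if len(fids) != 2:
            continue
        opp = []
        for fi in fids:
            opp.extend(w for w in faces[fi] if w != u and w != v)
        w, x = opp
        pu, pv, pw, px = points[u], points[v], points[w], points[x]
        nrm = np.cross(pv - pu, pw - pu)
        nn = np.linalg.norm(nrm)
        if nn < 1e-30:
            continue
        slack = abs(np.dot(nrm / nn, px - pu))
        if slack < DEGENERACY_SLACK:
            quads.add(tuple(sorted((u, v, w, x))))
    return sorted(quads)


def delaunay_on_sphere(positions: np.ndarray) -> SphericalTriangulation:
    """Delaunay triangulation of unit-sphere points via their convex hull.

    Requires >= 4 points not all on one great circle (non-coplanar).
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 4:
        raise DegenerateGeometryError("spherical Delaunay needs at least 4 points")
    try:
        hull = ConvexHull(positions, qhull_options="Qt")
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set for spherical Delaunay: {exc}") from exc
    if len(hull.vertices) != len(positions):
        raise DegenerateGeometryError(
            "some points fall inside the convex hull; input is not a valid spherical point set")
    faces = _orient_outward(positions, hull.simplices.astype(int))
    tri = SphericalTriangulation(points=positions, faces=faces)
    tri.ambiguous_quads = _near_degenerate_quads(positions, faces)
    if tri.euler_characteristic() != 2:
        raise DegenerateGeometryError("triangulation does not satisfy V - E + F = 2")
    return tri


@dataclass
class VoronoiCells:
    """Spherical Voronoi tessellation dual to the Delaunay triangulation.

    ``regions[i]`` lists indices into ``vertices`` walking the boundary of
    site i's cell in order; ``areas`` are solid angles summing to 4*pi.
    """

    vertices: np.ndarray
    regions: list[list[int]]
    areas: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.regions)


def voronoi_on_sphere(positions: np.ndarray) -> VoronoiCells:
    """Spherical Voronoi tessellation of unit-sphere points (one cell per site)."""
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 4:
        raise DegenerateGeometryError("spherical Voronoi needs at least 4 points")
    try:
        sv = SphericalVoronoi(positions, radius=1.0, threshold=1e-10)
    except ValueError as exc:
        raise DegenerateGeometryError(f"degenerate point set for spherical Voronoi: {exc}") from exc
    sv.sort_vertices_of_regions()
    return VoronoiCells(vertices=sv.vertices, regions=sv.regions,
                        areas=sv.calculate_areas())


def valences(tri: SphericalTriangulation) -> np.ndarray:
    """Per-vertex neighbor count (Delaunay degree = Voronoi edge count)."""
    return np.array([len(s) for s in tri.adjacency], dtype=int)


def valence_histogram(vals: np.ndarray) -> dict[int, int]:
    """Histogram N_i: number of cells having i neighbors."""
    return dict(sorted(Counter(int(v) for v in vals).items()))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def write_off(tri: SphericalTriangulation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{tri.n_vertices} {tri.n_faces} 0\n")
        for p in tri.points:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        for f in tri.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_ply(tri: SphericalTriangulation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {tri.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {tri.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p in tri.points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for f in tri.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_valence_histogram(hist: dict[int, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps({str(k): int(v) for k, v in hist.items()},
                                     indent=2, sort_keys=True) + "\n")
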