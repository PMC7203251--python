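"""One-sided (hemisphere) analysis of spherical monolayers.

Confocal images of a spherical monolayer show one hemisphere only.  The
workflow mirrors how such images are quantified: cell centers are Delaunay
triangulated; a maximally large analysis circle is chosen so that every cell
inside it is completely visible and has all its neighbors at least partially
visible (valences inside the circle are then free of boundary truncation);
the total cell number of the whole sphere is extrapolated from the ``n``
cells inside the circle of radius ``r`` on a sample of radius ``R`` as

    N_hat = 2 n / (1 - sqrt(1 - (r/R)^2)),

exact in expectation for an orthographic projection of a uniform spherical
layer; and the defectiveness of the circle is scaled by ``N_hat / n``.

Two entry points: :func:`analyze_view` validates the extrapolation on model
configurations with known ground truth, and :func:`analyze_centers` applies
the same pipeline to external 2D cell-center tables (CSV/TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .defects import q_minus
from .packing import DegenerateGeometryError, ParticleConfiguration
from .tessellation import SphericalTriangulation, delaunay_on_sphere, valence_histogram

__all__ = [
    "CellCenterTable",
    "HemisphereView",
    "CircleSelection",
    "SampleRadiusEstimate",
    "PlanarTriangulation",
    "HemisphereAnalysis",
    "project_hemisphere",
    "estimate_sample_radius",
    "triangulate_2d",
    "select_circle",
    "estimate_total_n",
    "extrapolate_q_minus",
    "analyze_view",
    "analyze_centers",
    "read_cell_centers",
    "write_cell_centers",
    "summarize_samples",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CellCenterTable:
    """2D cell-center coordinates for one imaged sample.

    ``visible`` marks completely visible cells (defaults to all True); units
    (um or px) are the caller's and must be shared by all coordinates.
    """

    coords: np.ndarray                    # (n, 2)
    sample_id: str = "sample"
    visible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if len(self.coords) < 4:
            raise ValueError("need at least 4 cell centers")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("duplicate cell centers")
        if self.visible is None:
            self.visible = np.ones(len(self.coords), dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
            if len(self.visible) != len(self.coords):
                raise ValueError("visible flag length mismatch")


@dataclass
class HemisphereView:
    """Orthographic projection of the visible hemisphere of a configuration."""

    axis: np.ndarray                      # unit view axis
    visible_indices: np.ndarray           # indices into the configuration
    coords: np.ndarray                    # (n_visible, 2) projected centers
    config: ParticleConfiguration = field(repr=False, default=None)

    @property
    def n_visible(self) -> int:
        return len(self.visible_indices)


@dataclass(frozen=True)
class CircleSelection:
    """Analysis circle: ``n`` centers strictly inside radius ``r``."""

    center: tuple[float, float]
    radius: float
    indices: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class SampleRadiusEstimate:
    """Estimated sample radius R and the method that produced it."""

    radius: float
    method: str


@dataclass
class PlanarTriangulation:
    """Planar Delaunay triangulation of projected/imaged cell centers.

    Valences are only meaningful away from the convex-hull boundary, where
    neighborhoods are not truncated by the edge of the data.
    """

    points: np.ndarray
    simplices: np.ndarray
    adjacency: list[set[int]]
    hull_indices: frozenset[int]
    ambiguous_quads: list[tuple[int, int, int, int]] = field(default_factory=list)

    def valences(self) -> np.ndarray:
        return np.array([len(s) for s in self.adjacency], dtype=int)


@dataclass
class HemisphereAnalysis:
    """Result of the one-sided pipeline on a view or a center table."""

    circle: CircleSelection
    sample_radius: SampleRadiusEstimate
    n_hat: float
    q_circle: int
    q_hat: float
    histogram_in_circle: dict[int, int]
    valences_in_circle: dict[int, int]    # center index -> valence
    sample_id: str = "sample"

    @property
    def n_hat_rounded(self) -> int:
        return int(round(self.n_hat))


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed in-plane basis orthogonal to ``axis``."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis[2]) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def project_hemisphere(config: ParticleConfiguration, axis) -> HemisphereView:
    """Orthographic projection of the particles on the open hemisphere
    facing ``axis`` (dot(position, axis) > 0)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("view axis must be a nonzero vector")
    axis = axis / norm
    dots = config.positions @ axis
    visible = np.flatnonzero(dots > 0)
    e1, e2 = _orthonormal_basis(axis)
    pts = config.positions[visible]
    coords = np.column_stack([pts @ e1, pts @ e2])
    return HemisphereView(axis=axis, visible_indices=visible, coords=coords,
                          config=config)


# ---------------------------------------------------------------------------
# Sample radius
# ---------------------------------------------------------------------------


def _convex_hull_2d(points: np.ndarray) -> np.ndarray:
    try:
        return ConvexHull(points).vertices
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate 2D point set: {exc}") from exc


def _min_width(hull_pts: np.ndarray) -> float:
    """Minimal width of a convex polygon (smallest visible diameter):
    min over edges of the farthest vertex distance from the edge line."""
    m = len(hull_pts)
    width = np.inf
    for i in range(m):
        a, b = hull_pts[i], hull_pts[(i + 1) % m]
        edge = b - a
        ln = np.linalg.norm(edge)
        if ln < 1e-30:
            continue
        normal = np.array([-edge[1], edge[0]]) / ln
        width = min(width, np.abs((hull_pts - a) @ normal).max())
    return float(width)


def estimate_sample_radius(points, method: str = "circular_fit") -> SampleRadiusEstimate:
    """Estimate the sample radius R from visible cell centers or boundary points.

    ``circular_fit``: radius of the minimal enclosing circle.
    ``elongated_mean``: (d_max + d_min) / 4 with d_max the largest and d_min
    the smallest visible diameter of the convex boundary.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points to estimate a radius")
    if method == "circular_fit":
        r = shapely.minimum_bounding_radius(shapely.MultiPoint(points))
        if not np.isfinite(r) or r <= 0:
            raise DegenerateGeometryError("minimal enclosing circle is degenerate")
        return SampleRadiusEstimate(radius=float(r), method=method)
    if method == "elongated_mean":
        hull_pts = points[_convex_hull_2d(points)]
        d2 = ((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2).sum(-1)
        d_max = float(np.sqrt(d2.max()))
        d_min = _min_width(hull_pts)
        return SampleRadiusEstimate(radius=(d_max + d_min) / 4.0, method=method)
    raise ValueError(f"unknown radius method {method!r}")


# ---------------------------------------------------------------------------
# Planar triangulation
# ---------------------------------------------------------------------------


def triangulate_2d(centers: np.ndarray) -> PlanarTriangulation:
    """Planar Delaunay triangulation of 2D centers.

    Cocircular quadruples (square-order regions) are resolved by Qhull's
    deterministic tie-break and reported in ``ambiguous_quads``.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 4:
        raise DegenerateGeometryError("planar triangulation needs at least 4 centers")
    try:
        dt = Delaunay(centers, qhull_options="Qbb Qc Qz Q12")
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate centers: {exc}") from exc
    simplices = dt.simplices.astype(int)
    adj = [set() for _ in range(len(centers))]
    for a, b, c in simplices:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    hull = frozenset(int(i) for i in np.unique(dt.convex_hull))
    return PlanarTriangulation(points=centers, simplices=simplices, adjacency=adj,
                               hull_indices=hull,
                               ambiguous_quads=_ambiguous_quads_2d(centers, dt))


def _ambiguous_quads_2d(points: np.ndarray, dt: Delaunay) -> list[tuple]:
    """Nearly cocircular quadruples across interior edges (in-circle test
    within slack 1e-9, scaled by the circumradius)."""
    quads = set()
    for fi, nbrs in enumerate(dt.neighbors):
        for k, fj in enumerate(nbrs):
            if fj < fi:
                continue
            tri_i = dt.simplices[fi]
            opp = [v for v in dt.simplices[fj] if v not in tri_i]
            if len(opp) != 1:
                continue
            a, b, c = points[tri_i]
            d = points[opp[0]]
            mat = np.array([
                [a[0] - d[0], a[1] - d[1], (a - d) @ (a - d)],
                [b[0] - d[0], b[1] - d[1], (b - d) @ (b - d)],
                [c[0] - d[0], c[1] - d[1], (c - d) @ (c - d)],
            ])
            scale = max(np.abs(mat).max(), 1e-30) ** 3
            if abs(np.linalg.det(mat)) / scale < 1e-9:
                quads.add(tuple(sorted((*map(int, tri_i), int(opp[0])))))
    return sorted(quads)


# ---------------------------------------------------------------------------
# Analysis circle and extrapolation
# ---------------------------------------------------------------------------


def select_circle(coords: np.ndarray, admissible: np.ndarray,
                  center=(0.0, 0.0)) -> CircleSelection:
    """Largest concentric circle containing admissible centers only.

    The radius is the distance from ``center`` to the nearest inadmissible
    center (or just beyond the farthest center when all are admissible);
    included are all centers strictly inside.
    """
    coords = np.asarray(coords, dtype=float)
    admissible = np.asarray(admissible, dtype=bool)
    center = np.asarray(center, dtype=float)
    rho = np.linalg.norm(coords - center, axis=1)
    if (~admissible).any():
        radius = float(rho[~admissible].min())
    else:
        radius = float(rho.max()) * (1 + 1e-9)
    inside = np.flatnonzero(rho < radius)
    if len(inside) == 0:
        raise ValueError("no admissible analysis circle (no centers inside)")
    return CircleSelection(center=(float(center[0]), float(center[1])),
                           radius=radius, indices=tuple(int(i) for i in inside))


def estimate_total_n(n: int, r: float, big_r: float) -> float:
    """Extrapolated total cell number of the sphere from the ``n`` cells in
    an analysis circle of radius ``r`` on a sample of radius ``R``:
    2n / (1 - sqrt(1 - (r/R)^2))."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 < r <= big_r:
        raise ValueError(f"need 0 < r <= R, got r={r}, R={big_r}")
    ratio = r / big_r
    return 2.0 * n / (1.0 - np.sqrt(max(0.0, 1.0 - ratio * ratio)))


def extrapolate_q_minus(q_circle: float, n: int, n_hat: float) -> float:
    """Whole-sphere defectiveness: circle defectiveness scaled by N_hat / n."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return q_circle * n_hat / n


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


def _complete_visibility(config: ParticleConfiguration, tri: SphericalTriangulation,
                         axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(visible, completely_visible, partially_visible) masks for a model
    configuration.

    A cell is completely visible when its whole Voronoi cell lies in the
    open hemisphere, i.e. all circumcenters of its incident Delaunay faces
    (its Voronoi vertices) have positive dot product with the view axis;
    it is at least partially visible when any of them does (or its center
    is visible).
    """
    dots = config.positions @ axis
    visible = dots > 0
    cc = tri.face_circumcenters() @ axis
    completely = visible.copy()
    partially = visible.copy()
    for fi, face in enumerate(tri.faces):
        if cc[fi] <= 0:
            completely[face] = False
        else:
            partially[face] = True
    return visible, completely, partially


def analyze_view(config: ParticleConfiguration, axis=(0.0, 0.0, 1.0),
                 tri: SphericalTriangulation | None = None) -> HemisphereAnalysis:
    """One-sided analysis of a model configuration with known geometry.

    Admissible cells are completely visible and have every spherical
    Delaunay neighbor at least partially visible (so their valences could be
    read off a one-sided image); the analysis circle is centered on the
    projected pole and the true sphere radius (1) is used for R.  Valences
    inside the circle are the true spherical ones.
    """
    if tri is None:
        tri = delaunay_on_sphere(config.positions)
    view = project_hemisphere(config, axis)
    visible, completely, partially = _complete_visibility(config, tri, view.axis)
    admissible_vis = np.array([
        completely[i] and all(partially[j] for j in tri.adjacency[i])
        for i in view.visible_indices
    ])
    circle = select_circle(view.coords, admissible_vis)
    included = [int(view.visible_indices[k]) for k in circle.indices]
    vals = {i: len(tri.adjacency[i]) for i in included}
    hist = valence_histogram(np.array(list(vals.values())))
    q_c = q_minus(hist)
    n_hat = estimate_total_n(circle.n, circle.radius, 1.0)
    return HemisphereAnalysis(
        circle=CircleSelection(circle.center, circle.radius, tuple(included)),
        sample_radius=SampleRadiusEstimate(radius=1.0, method="known_sphere"),
        n_hat=n_hat, q_circle=q_c,
        q_hat=extrapolate_q_minus(q_c, circle.n, n_hat),
        histogram_in_circle=hist, valences_in_circle=vals,
    )


def analyze_centers(table: CellCenterTable,
                    radius_method: str = "circular_fit") -> HemisphereAnalysis:
    """One-sided analysis of an external 2D cell-center table.

    Without 3D information, a center is admissible when it is marked visible,
    lies off the convex hull of the data, and none of its planar Delaunay
    neighbors lies on the hull (so its valence is free of boundary
    truncation).  The circle is centered on the centroid of the centers and
    R comes from :func:`estimate_sample_radius`.
    """
    tri2d = triangulate_2d(table.coords)
    hull = tri2d.hull_indices
    admissible = np.array([
        bool(table.visible[i]) and i not in hull
        and not any(j in hull for j in tri2d.adjacency[i])
        for i in range(len(table.coords))
    ])
    centroid = table.coords.mean(axis=0)
    circle = select_circle(table.coords, admissible, center=centroid)
    big_r = estimate_sample_radius(table.coords, method=radius_method)
    vals = {i: len(tri2d.adjacency[i]) for i in circle.indices}
    hist = valence_histogram(np.array(list(vals.values())))
    q_c = q_minus(hist)
    r_eff = min(circle.radius, big_r.radius)
    n_hat = estimate_total_n(circle.n, r_eff, big_r.radius)
    return HemisphereAnalysis(
        circle=circle, sample_radius=big_r, n_hat=n_hat, q_circle=q_c,
        q_hat=extrapolate_q_minus(q_c, circle.n, n_hat),
        histogram_in_circle=hist, valences_in_circle=vals,
        sample_id=table.sample_id,
    )


# ---------------------------------------------------------------------------
# Table I/O and group summaries
# ---------------------------------------------------------------------------


def read_cell_centers(path: str | Path) -> list[CellCenterTable]:
    """Read cell-center tables from CSV/TSV (columns sample_id, x, y[, visible];
    delimiter autodetected); one table per sample_id, in file order."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"cell-center table needs columns {sorted(required)}")
    tables = []
    for sid in df["sample_id"].drop_duplicates():
        sub = df[df["sample_id"] == sid]
        vis = sub["visible"].to_numpy(bool) if "visible" in df.columns else None
        tables.append(CellCenterTable(
            coords=sub[["x", "y"]].to_numpy(float), sample_id=str(sid), visible=vis))
    return tables


def write_cell_centers(table: CellCenterTable, path: str | Path) -> None:
    df = pd.DataFrame({
        "sample_id": table.sample_id,
        "x": table.coords[:, 0],
        "y": table.coords[:, 1],
        "visible": table.visible.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.17g")


def summarize_samples(records) -> pd.DataFrame:
    """Comparative per-group summary of per-sample (N, Q_minus) results.

    ``records``: DataFrame (or list of dicts) with columns ``group``, ``n``
    and ``q_minus``.  Returns one row per group with <N>, the N range, the
    number of samples, <Q_minus>, the Q_minus range and <Q_minus>/<N>,
    ordered by increasing relative defectiveness.
    """
    df = pd.DataFrame(records)
    missing = {"group", "n", "q_minus"} - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("need at least one sample")
    out = df.groupby("group").agg(
        n_mean=("n", "mean"), n_min=("n", "min"), n_max=("n", "max"),
        n_samples=("n", "size"),
        q_minus_mean=("q_minus", "mean"),
        q_minus_min=("q_minus", "min"), q_minus_max=("q_minus", "max"),
    ).reset_index()
    out["relative_defectiveness"] = out["q_minus_mean"] / out["n_mean"]
    return out.sort_values("relative_defectiveness", kind="stable",
                           ignore_index=True)
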