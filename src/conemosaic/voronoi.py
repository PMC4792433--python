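"""Voronoi-domain statistics of a cone mosaic sampling field.

The analysis follows the classic Voronoi-domain (VD) approach to mosaic
regularity: tessellate the field, one convex domain per cell, clip the
tessellation to the rectangular sampling window, discard cells whose
domains are distorted by the window border, and summarise the remaining
domain areas by

* the planimetric cell density (all cells over the window area),
* the skewness g1 of the domain-area distribution (third standardised
  central moment, 1/n convention), which picks up the long right tail
  produced by cell-free patches, and
* the coefficient of clustering (CC): the global coefficient of variation
  of domain areas divided by the mean, over cells, of the local
  coefficient of variation among each cell's Voronoi neighbours,

      CC = (sigma_x / mean_x) / [ (1/n) * sum_i sigma_ai / mean_ai ] ,

  where x runs over retained domain areas and, for cell i, mean_ai and
  sigma_ai are the mean and SD of the areas of the domains adjacent to i.
  For a statistically homogeneous mosaic local and global variation agree
  and CC is near 1; when small and large domains segregate spatially
  (cells crowded on rims of cell-free holes) the local variation is
  suppressed relative to the global one and CC rises well above 1.

Window clipping is exact: the tessellation of the point set augmented with
its mirror images across the four window edges, restricted to the window,
coincides with the clipped tessellation of the original points (for any
point p and its reflection p' across an edge, locations inside the window
are never closer to p' than to p).  Each original cell is therefore a
bounded convex polygon contained in the window, the polygons partition the
window exactly, and shared edges are already clipped.  Rasterised
nearest-point assignment is deliberately left to the test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, Voronoi

from .exceptions import (
    ClusteringUndefinedError,
    DegenerateGeometryError,
    InsufficientInteriorCellsError,
    InsufficientPointsError,
    ZeroVarianceError,
)
from .io_coords import PointField

#: Shared Voronoi edges shorter than this (micrometres) do not count as adjacency.
EDGE_TOL = 1e-9

#: Relative tolerance for the partition check (sum of areas vs window area).
PARTITION_RTOL = 1e-6


@dataclass
class VoronoiResult:
    """Clipped Voronoi tessellation of one field.

    Attributes
    ----------
    areas : (n,) array
        Polygon area of each cell's clipped domain, um^2, in field order.
    interior : (n,) bool array
        True for cells retained for statistics (not boundary-affected).
    neighbors : list of (k_i,) int arrays
        Indices of cells sharing a polygon edge of positive length with
        cell i (the cell itself is never its own neighbour).
    boundary_touch : (n,) bool array
        True if the cell's clipped polygon meets the window boundary.
    polygons : list of (m_i, 2) arrays
        Counter-clockwise vertices of each clipped domain.
    window : tuple
        The clipping rectangle (x_min, y_min, x_max, y_max).
    """

    areas: np.ndarray
    interior: np.ndarray
    neighbors: list[np.ndarray]
    boundary_touch: np.ndarray
    polygons: list[np.ndarray] = dataclass_field(repr=False, default_factory=list)
    window: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.areas)

    @property
    def n_interior(self) -> int:
        return int(self.interior.sum())


def _mirror_points(pts: np.ndarray, window: tuple) -> np.ndarray:
    x0, y0, x1, y1 = window
    left = np.column_stack([2 * x0 - pts[:, 0], pts[:, 1]])
    right = np.column_stack([2 * x1 - pts[:, 0], pts[:, 1]])
    bottom = np.column_stack([pts[:, 0], 2 * y0 - pts[:, 1]])
    top = np.column_stack([pts[:, 0], 2 * y1 - pts[:, 1]])
    return np.vstack([pts, left, right, bottom, top])


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def compute_voronoi(field: PointField) -> VoronoiResult:
    """Tessellate a field and clip every domain to the sampling window.

    Unbounded domains are made finite by the mirror construction described
    in the module docstring; the returned polygons partition the window
    (sum of areas equals the window area to ~1e-6 relative).

    Raises
    ------
    InsufficientPointsError
        Fewer than 4 points.
    DegenerateGeometryError
        All points collinear (no 2-D tessellation exists).
    """
    pts = field.points
    n = len(pts)
    if n < 4:
        raise InsufficientPointsError(f"Voronoi analysis needs >= 4 points, got {n}")
    centered = pts - pts.mean(axis=0)
    # smallest singular value ~ 0 iff all points lie on one line
    if np.linalg.svd(centered, compute_uv=False)[-1] < 1e-9 * max(
        1.0, np.abs(centered).max()
    ):
        raise DegenerateGeometryError("all points are (nearly) collinear")
    try:
        vor = Voronoi(_mirror_points(pts, field.window))
    except QhullError as exc:
        raise DegenerateGeometryError(f"Qhull failed on degenerate input: {exc}") from exc

    x0, y0, x1, y1 = field.window
    polygons: list[np.ndarray] = []
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region:  # cannot happen for mirrored interior points
            raise DegenerateGeometryError(f"unbounded region for point {i}")
        verts = vor.vertices[region]
        # regions are convex: order vertices CCW around the site
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        verts = verts[np.argsort(ang)]
        polygons.append(verts)
        areas[i] = _shoelace(verts)

    ridge_points = vor.ridge_points
    neighbor_lists: list[list[int]] = [[] for _ in range(n)]
    boundary_touch = np.zeros(n, dtype=bool)
    for (p, q), rv in zip(ridge_points, vor.ridge_vertices):
        p, q = int(p), int(q)
        if p >= n and q >= n:
            continue
        if -1 in rv:
            # unbounded ridge between a mirror pair; only flags boundary contact
            length = np.inf
        else:
            a, b = vor.vertices[rv[0]], vor.vertices[rv[1]]
            length = float(np.hypot(*(a - b)))
        if length <= EDGE_TOL:
            continue
        if p < n and q < n:
            neighbor_lists[p].append(q)
            neighbor_lists[q].append(p)
        else:  # ridge against a mirror image: the cell touches the window edge
            boundary_touch[p if p < n else q] = True

    # corner contacts (single-vertex touch) are not caught by mirror ridges
    for i, verts in enumerate(polygons):
        if boundary_touch[i]:
            continue
        on = (
            (np.abs(verts[:, 0] - x0) < EDGE_TOL)
            | (np.abs(verts[:, 0] - x1) < EDGE_TOL)
            | (np.abs(verts[:, 1] - y0) < EDGE_TOL)
            | (np.abs(verts[:, 1] - y1) < EDGE_TOL)
        )
        if on.any():
            boundary_touch[i] = True

    neighbors = [np.array(sorted(set(lst)), dtype=int) for lst in neighbor_lists]
    return VoronoiResult(
        areas=areas,
        interior=~boundary_touch,
        neighbors=neighbors,
        boundary_touch=boundary_touch,
        polygons=polygons,
        window=field.window,
    )


def interior_mask(
    vr: VoronoiResult, field: PointField, rule: str = "window_touch"
) -> np.ndarray:
    """Mark cells retained for statistics under a boundary-exclusion rule.

    ``window_touch`` (default) drops every cell whose clipped polygon meets
    the window boundary (equivalently, whose unclipped domain is unbounded
    or cut by the window).  ``hull_peel`` drops the cells lying on the
    convex hull of the point set.  The mask is stored on ``vr.interior``
    and returned.
    """
    if rule == "window_touch":
        mask = ~vr.boundary_touch
    elif rule == "hull_peel":
        mask = np.ones(vr.n, dtype=bool)
        hull = ConvexHull(field.points)
        mask[hull.vertices] = False
    else:
        raise ValueError(f"unknown edge rule {rule!r} (window_touch or hull_peel)")
    vr.interior = mask
    return mask


def density(field: PointField) -> float:
    """Planimetric cell density, cells per mm^2 of sampling window.

    All cells in the field are counted; boundary exclusion applies only to
    the Voronoi statistics, not to the count.
    """
    return field.n / field.window_area_mm2


def skewness_g1(values: np.ndarray) -> float:
    """Skewness g1 = m3 / m2^(3/2) with biased (1/n) central moments.

    Both moments use the 1/n convention, so g1 is the third standardised
    moment of the empirical distribution.  Requires >= 3 values with
    nonzero spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientPointsError(f"skewness needs >= 3 values, got {x.size}")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 <= 0:
        raise ZeroVarianceError("skewness undefined: all values are equal")
    return float(np.mean(d**3) / m2**1.5)


def _sd(x: np.ndarray, convention: str) -> float:
    if convention == "sample":
        return float(x.std(ddof=1))
    if convention == "population":
        return float(x.std(ddof=0))
    raise ValueError(f"unknown sd convention {convention!r} (sample or population)")


def coefficient_of_clustering(
    vr: VoronoiResult,
    *,
    sd_convention: str = "sample",
    cc_neighbors: str = "all",
    min_cells: int = 10,
) -> float:
    """Coefficient of clustering of the retained Voronoi-domain areas.

    CC is the global coefficient of variation of the retained areas
    divided by the average local coefficient of variation over each
    retained cell's neighbour areas (see module docstring).  Neighbour
    sets come from Voronoi adjacency; with ``cc_neighbors="all"``
    (default) a retained cell's neighbourhood may include
    boundary-flagged cells (their clipped areas), while
    ``"interior_only"`` restricts neighbourhoods to retained cells.

    Cells with fewer than 2 eligible neighbours, or a non-positive
    neighbourhood mean, are dropped from the local average with a warning.

    Raises
    ------
    InsufficientInteriorCellsError
        Fewer than ``min_cells`` retained cells.
    ZeroVarianceError
        All retained areas equal (global CV is 0/undefined ratio).
    ClusteringUndefinedError
        Every retained cell was dropped from the local average.
    """
    if cc_neighbors not in {"all", "interior_only"}:
        raise ValueError(f"unknown cc_neighbors {cc_neighbors!r}")
    idx = np.flatnonzero(vr.interior)
    if idx.size < min_cells:
        raise InsufficientInteriorCellsError(
            f"insufficient interior cells for CC: {idx.size} < {min_cells}"
        )
    x = vr.areas[idx]
    sigma_x = _sd(x, sd_convention)
    if sigma_x <= 0:
        raise ZeroVarianceError("CC undefined: all retained domain areas are equal")
    global_cv = sigma_x / x.mean()

    local_cvs = []
    dropped = 0
    for i in idx:
        nb = vr.neighbors[i]
        if cc_neighbors == "interior_only":
            nb = nb[vr.interior[nb]]
        if nb.size < 2:
            dropped += 1
            continue
        a = vr.areas[nb]
        mean_a = a.mean()
        if mean_a <= 0:
            dropped += 1
            continue
        local_cvs.append(_sd(a, sd_convention) / mean_a)
    if dropped:
        warnings.warn(
            f"{dropped} cell(s) dropped from the local CV average "
            "(fewer than 2 eligible neighbours or zero neighbourhood mean)",
            stacklevel=2,
        )
    if not local_cvs:
        raise ClusteringUndefinedError("CC undefined: no cell retains a usable neighbourhood")
    mean_local = float(np.mean(local_cvs))
    if mean_local <= 0:
        raise ClusteringUndefinedError("CC undefined: mean local CV is zero")
    return float(global_cv / mean_local)


@dataclass
class MosaicStatistics:
    """Scalar summaries of one sampling field."""

    n_total: int
    n_interior: int
    density: float  # cells / mm^2
    areas_interior: np.ndarray  # um^2, the histogram input
    skewness_g1: float
    cc: float

    def to_dict(self) -> dict:
        """Flat record (without the area vector) for tabular output."""
        return {
            "n_total": self.n_total,
            "n_interior": self.n_interior,
            "density": self.density,
            "skewness_g1": self.skewness_g1,
            "cc": self.cc,
        }


def analyze_field(
    field: PointField,
    *,
    edge_rule: str = "window_touch",
    sd_convention: str = "sample",
    cc_neighbors: str = "all",
    min_interior: int = 10,
) -> MosaicStatistics:
    """Full Voronoi-domain analysis of one field.

    Deterministic given the field and options; composes
    :func:`compute_voronoi`, :func:`interior_mask`, :func:`density`,
    :func:`skewness_g1` and :func:`coefficient_of_clustering`.
    """
    vr = compute_voronoi(field)
    mask = interior_mask(vr, field, rule=edge_rule)
    n_int = int(mask.sum())
    if n_int < 3:
        raise InsufficientInteriorCellsError(
            f"insufficient interior cells: {n_int} remain after {edge_rule} exclusion"
        )
    areas_int = vr.areas[mask]
    return MosaicStatistics(
        n_total=field.n,
        n_interior=n_int,
        density=density(field),
        areas_interior=areas_int,
        skewness_g1=skewness_g1(areas_int),
        cc=coefficient_of_clustering(
            vr,
            sd_convention=sd_convention,
            cc_neighbors=cc_neighbors,
            min_cells=min_interior,
        ),
    )
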