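"""Independent oracles for the Voronoi-domain statistics.

Two routes, both independent of the package's mirror-point Qhull path:

* half-plane construction: each cell is the window rectangle clipped by
  the perpendicular-bisector half-plane against every other point
  (Sutherland–Hodgman); exact up to float rounding.
* raster construction: assign every pixel centre of a fine grid to its
  nearest point; areas are pixel counts, adjacency comes from 4-connected
  label contacts.

The clustering-coefficient formula is re-evaluated here from the oracle's
own geometry (duplicated on purpose — the oracle must not call into the
package).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Keep the part of a convex polygon where a.q <= b (Sutherland–Hodgman)."""
    if len(poly) == 0:
        return poly
    out = []
    vals = poly @ a - b
    m = len(poly)
    for i in range(m):
        j = (i + 1) % m
        pi, pj = poly[i], poly[j]
        vi, vj = vals[i], vals[j]
        if vi <= 0:
            out.append(pi)
        if (vi < 0 < vj) or (vj < 0 < vi):
            t = vi / (vi - vj)
            out.append(pi + t * (pj - pi))
    return np.asarray(out) if out else np.empty((0, 2))


def halfplane_cells(points: np.ndarray, window) -> list[np.ndarray]:
    """Clipped Voronoi cell polygons by brute-force half-plane intersection."""
    x0, y0, x1, y1 = window
    rect = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)
    pts = np.asarray(points, dtype=float)
    cells = []
    for i, p in enumerate(pts):
        poly = rect
        for j, q in enumerate(pts):
            if j == i:
                continue
            a = q - p
            b = a @ (p + q) / 2.0
            poly = _clip_halfplane(poly, a, b)
        cells.append(poly)
    return cells


def polygon_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def halfplane_areas(points, window) -> np.ndarray:
    return np.array([polygon_area(c) for c in halfplane_cells(points, window)])


def halfplane_adjacency(points, window, tol: float = 1e-9) -> list[set[int]]:
    """Adjacency from the half-plane cells via the equidistance property.

    A polygon edge of cell i lies on the bisector against point j iff both
    endpoints are (numerically) equidistant from p_i and p_j and no other
    point is closer; summing those edge lengths per pair gives the shared
    boundary length.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    cells = halfplane_cells(pts, window)
    scale = max(abs(window[2] - window[0]), abs(window[3] - window[1]))
    eq_tol = 1e-7 * scale
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, poly in enumerate(cells):
        m = len(poly)
        if m < 2:
            continue
        d = cdist(poly, pts)  # vertex-to-site distances
        for e in range(m):
            v1, v2 = e, (e + 1) % m
            length = float(np.hypot(*(poly[v1] - poly[v2])))
            if length <= tol:
                continue
            for j in range(n):
                if j == i:
                    continue
                if (
                    abs(d[v1, i] - d[v1, j]) < eq_tol
                    and abs(d[v2, i] - d[v2, j]) < eq_tol
                ):
                    nbrs[i].add(j)
                    nbrs[j].add(i)
    return nbrs


def halfplane_boundary_touch(points, window, tol: float = 1e-9) -> np.ndarray:
    x0, y0, x1, y1 = window
    cells = halfplane_cells(points, window)
    touch = np.zeros(len(cells), dtype=bool)
    for i, c in enumerate(cells):
        if len(c) == 0:
            continue
        on = (
            (np.abs(c[:, 0] - x0) < tol)
            | (np.abs(c[:, 0] - x1) < tol)
            | (np.abs(c[:, 1] - y0) < tol)
            | (np.abs(c[:, 1] - y1) < tol)
        )
        touch[i] = bool(on.any())
    return touch


def raster_assign(points, window, resolution: float) -> np.ndarray:
    """Label image assigning each pixel centre to its nearest point."""
    x0, y0, x1, y1 = window
    xs = np.arange(x0 + resolution / 2, x1, resolution)
    ys = np.arange(y0 + resolution / 2, y1, resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    labels = np.argmin(cdist(grid, np.asarray(points, dtype=float)), axis=1)
    return labels.reshape(len(ys), len(xs))


def raster_areas(labels: np.ndarray, n_points: int, resolution: float) -> np.ndarray:
    counts = np.bincount(labels.ravel(), minlength=n_points)
    return counts * resolution**2


def raster_adjacency(labels: np.ndarray, n_points: int, min_contacts: int = 3) -> list[set[int]]:
    """4-connected label contacts; short accidental contacts are ignored."""
    pairs = {}
    for a, b in [
        (labels[:, :-1].ravel(), labels[:, 1:].ravel()),
        (labels[:-1, :].ravel(), labels[1:, :].ravel()),
    ]:
        diff = a != b
        for i, j in zip(a[diff], b[diff]):
            key = (min(i, j), max(i, j))
            pairs[key] = pairs.get(key, 0) + 1
    nbrs: list[set[int]] = [set() for _ in range(n_points)]
    for (i, j), c in pairs.items():
        if c >= min_contacts:
            nbrs[int(i)].add(int(j))
            nbrs[int(j)].add(int(i))
    return nbrs


def raster_boundary_touch(labels: np.ndarray, n_points: int) -> np.ndarray:
    touch = np.zeros(n_points, dtype=bool)
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        touch[np.unique(edge)] = True
    return touch


def clustering_coefficient(
    areas: np.ndarray,
    neighbors: list[set[int]],
    keep: np.ndarray | None = None,
    ddof: int = 1,
) -> float:
    """Global CV over kept areas divided by mean local CV over neighbour areas."""
    areas = np.asarray(areas, dtype=float)
    idx = np.arange(len(areas)) if keep is None else np.flatnonzero(keep)
    x = areas[idx]
    global_cv = x.std(ddof=ddof) / x.mean()
    local = []
    for i in idx:
        nb = np.fromiter(neighbors[i], dtype=int)
        if nb.size < 2:
            continue
        a = areas[nb]
        local.append(a.std(ddof=ddof) / a.mean())
    return float(global_cv / np.mean(local))


def skewness_oracle(values) -> float:
    """g1 via scipy's biased skewness (the printed 1/n convention)."""
    from scipy.stats import skew

    return float(skew(np.asarray(values, dtype=float), bias=True))
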