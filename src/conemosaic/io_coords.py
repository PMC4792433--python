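"""Reading, writing and extraction of cone-mosaic cell coordinates.

A sampling field is a rectangular patch of retina (the study protocol uses
1x1 mm squares) over which every cone cell body has been annotated, either
as a row in a coordinate table or as a white dot painted on a binary
annotation image.  This module turns those artefacts into :class:`PointField`
objects, the input of every downstream statistic.

Coordinates are continuous Cartesian, in micrometres, origin at the
bottom-left corner of the window with y increasing upward.  Dot-image
centroids (row/column order, y down) are converted to this convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .exceptions import (
    CoordinateParseError,
    InsufficientPointsError,
    NoDotsDetectedError,
)

#: Points closer than this (micrometres) are treated as exact duplicates.
DUPLICATE_TOL = 1e-9

_WINDOW_TOL = 1e-9


@dataclass
class PointField:
    """A set of 2-D cell positions plus its rectangular sampling window.

    Parameters
    ----------
    points : (n, 2) array of float
        Cell-body positions in micrometres.
    window : tuple of float
        Axis-aligned sampling rectangle ``(x_min, y_min, x_max, y_max)``
        in micrometres.  Every point must lie inside or on it.
    label : str
        Free-text condition tag (e.g. ``"control"``).
    animal_id : str
        Free-text identifier of the animal / preparation.
    unit_scale : float
        Micrometres per original coordinate unit; recorded for provenance
        (the stored coordinates are already scaled).
    """

    points: np.ndarray
    window: tuple[float, float, float, float]
    label: str = ""
    animal_id: str = ""
    unit_scale: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        x0, y0, x1, y1 = (float(v) for v in self.window)
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"window must have positive extent, got {self.window}")
        self.window = (x0, y0, x1, y1)
        if len(pts):
            inside = (
                (pts[:, 0] >= x0 - _WINDOW_TOL)
                & (pts[:, 0] <= x1 + _WINDOW_TOL)
                & (pts[:, 1] >= y0 - _WINDOW_TOL)
                & (pts[:, 1] <= y1 + _WINDOW_TOL)
            )
            if not inside.all():
                bad = int(np.flatnonzero(~inside)[0])
                raise ValueError(
                    f"point {bad} at {tuple(pts[bad])} lies outside window {self.window}"
                )
            pairs = cKDTree(pts).query_pairs(DUPLICATE_TOL)
            if pairs:
                i, j = sorted(next(iter(pairs)))
                raise ValueError(
                    f"points {i} and {j} coincide (closer than {DUPLICATE_TOL} um); "
                    "deduplicate first (see deduplicate_points)"
                )

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def window_area_um2(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)

    @property
    def window_area_mm2(self) -> float:
        return self.window_area_um2 / 1e6

    def with_window(self, window: tuple[float, float, float, float]) -> "PointField":
        """Return a copy with a different sampling window (re-validated)."""
        return PointField(self.points.copy(), window, self.label, self.animal_id, self.unit_scale)


def deduplicate_points(points: np.ndarray, tol: float = DUPLICATE_TOL) -> np.ndarray:
    """Drop later members of coincident point pairs, warning if any are found."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts
    pairs = cKDTree(pts).query_pairs(tol)
    if not pairs:
        return pts
    drop = {max(i, j) for i, j in pairs}
    warnings.warn(
        f"removed {len(drop)} duplicate point(s) (pairwise distance < {tol} um)",
        stacklevel=2,
    )
    keep = np.ones(len(pts), dtype=bool)
    keep[list(drop)] = False
    return pts[keep]


def _bounding_window(pts: np.ndarray) -> tuple[float, float, float, float]:
    """Tight bounding box expanded outward to whole micrometres."""
    x0 = math.floor(pts[:, 0].min())
    y0 = math.floor(pts[:, 1].min())
    x1 = math.ceil(pts[:, 0].max())
    y1 = math.ceil(pts[:, 1].max())
    if x1 == x0:
        x1 += 1
    if y1 == y0:
        y1 += 1
    return (float(x0), float(y0), float(x1), float(y1))


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        f = format.lower()
        if f not in {"csv", "tsv", "xlsx"}:
            raise ValueError(f"unsupported format {format!r}")
        return f
    suffix = path.suffix.lower()
    return {".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx", ".xls": "xlsx"}.get(suffix, "csv")


def _extract_xy(raw: pd.DataFrame, path: Path) -> np.ndarray:
    """First two fully numeric columns become x and y; header row auto-dropped."""
    if raw.empty:
        raise CoordinateParseError(f"{path}: no rows")
    first = raw.iloc[0]
    header = False
    for v in first:
        if isinstance(v, str):
            try:
                float(v)
            except ValueError:
                header = True
                break
    body = raw.iloc[1:] if header else raw
    offset = 2 if header else 1  # 1-based row number of first data row
    numeric_cols = []
    partial: tuple[int, int] | None = None  # (column, failing row) for diagnostics
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        orig_na = body[col].isna()
        bad = converted.isna() & ~orig_na
        if bad.any():
            if partial is None:
                partial = (int(col), int(np.flatnonzero(bad.to_numpy())[0]) + offset)
            continue
        if converted.isna().any():
            continue  # blank cells: not a coordinate column
        numeric_cols.append(converted.to_numpy(dtype=float))
        if len(numeric_cols) == 2:
            break
    if len(numeric_cols) < 2:
        if partial is not None:
            col, row = partial
            raise CoordinateParseError(
                f"{path}: non-numeric cell in column {col} at row {row}"
            )
        raise CoordinateParseError(f"{path}: fewer than two numeric columns")
    return np.column_stack(numeric_cols)


def read_coordinates(
    path: str | Path,
    format: str | None = None,
    *,
    window: tuple[float, float, float, float] | None = None,
    unit_scale: float = 1.0,
    sheet: str | int | None = None,
    label: str = "",
    animal_id: str = "",
) -> PointField:
    """Read a cell-coordinate table into a :class:`PointField`.

    The supplementary-table dialect is permissive: one field per file (or
    per worksheet), a header row is optional and auto-detected, and the
    first two fully numeric columns are taken as x and y.  Coordinates are
    multiplied by ``unit_scale`` (micrometres per input unit).  If no
    ``window`` is given, the tight bounding box of the points, expanded to
    whole micrometres, is used.

    Raises
    ------
    CoordinateParseError
        Non-numeric cells in a coordinate column (the row is named).
    InsufficientPointsError
        Fewer than 4 points: the Voronoi tessellation is undefined.
    """
    path = Path(path)
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    fmt = _infer_format(path, format)
    try:
        if fmt == "xlsx":
            raw = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0, header=None)
        else:
            raw = pd.read_csv(
                path, sep="\t" if fmt == "tsv" else ",", header=None, dtype=str,
                skip_blank_lines=True, comment="#",
            )
    except FileNotFoundError:
        raise
    except OSError:
        raise
    except Exception as exc:  # malformed container → parse error
        raise CoordinateParseError(f"{path}: {exc}") from exc

    pts = _extract_xy(raw, path) * float(unit_scale)
    pts = deduplicate_points(pts)
    if len(pts) < 4:
        raise InsufficientPointsError(
            f"{path}: {len(pts)} point(s); at least 4 are required for Voronoi analysis"
        )
    win = window if window is not None else _bounding_window(pts)
    return PointField(pts, win, label=label, animal_id=animal_id, unit_scale=float(unit_scale))


def write_coordinates(field: PointField, path: str | Path, format: str | None = None) -> None:
    """Write a field's coordinates as a two-column ``x,y`` table.

    Full float precision is kept so that read→write→read round-trips
    reproduce coordinates to well below 1e-6 um.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xlsx":
        raise ValueError("write_coordinates supports csv and tsv only")
    df = pd.DataFrame({"x": field.points[:, 0], "y": field.points[:, 1]})
    df.to_csv(path, sep="\t" if fmt == "tsv" else ",", index=False, float_format="%.10g")


def detect_dots(
    image: np.ndarray,
    threshold: float,
    min_area_px: int = 1,
    pixel_size_um: float = 1.0,
) -> PointField:
    """Extract cell positions from a white-dot annotation image.

    The image is normalised to [0, 1] by its maximum, thresholded, and the
    centroid of each connected component with at least ``min_area_px``
    pixels becomes one cell position.  Pixel (r, c) is taken to cover the
    square [c, c+1] x [rows-r-1, rows-r] in pixel units, so the image row
    axis (y down) maps to Cartesian y up; the window is the full image
    extent in micrometres.
    """
    from skimage import measure

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    peak = img.max() if img.size else 0.0
    if img.size == 0 or peak <= 0:
        raise NoDotsDetectedError("image is empty or entirely black")
    mask = (img / peak) >= threshold
    labels = measure.label(mask, connectivity=2)
    rows, cols = img.shape
    centroids = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        r, c = region.centroid
        centroids.append(((c + 0.5) * pixel_size_um, (rows - r - 0.5) * pixel_size_um))
    if not centroids:
        raise NoDotsDetectedError(
            f"no dots detected (threshold={threshold}, min_area_px={min_area_px})"
        )
    window = (0.0, 0.0, cols * pixel_size_um, rows * pixel_size_um)
    return PointField(np.asarray(centroids), window, unit_scale=pixel_size_um)
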