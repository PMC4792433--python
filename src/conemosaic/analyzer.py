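"""Estimator-style front end to the per-field Voronoi-domain analysis."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .io_coords import PointField
from .voronoi import (
    MosaicStatistics,
    coefficient_of_clustering,
    compute_voronoi,
    density,
    interior_mask,
    skewness_g1,
)


class MosaicAnalyzer(BaseEstimator):
    """Compute Voronoi-domain statistics of a 2-D cell mosaic.

    Scikit-learn-style estimator: ``fit`` takes the cell positions of one
    sampling field and computes the fitted statistics; parameters are the
    analysis options and travel through ``get_params`` / ``set_params``,
    so the analyzer composes with sklearn model-selection utilities.

    Parameters
    ----------
    edge_rule : {"window_touch", "hull_peel"}
        Boundary-exclusion rule. ``window_touch`` drops cells whose
        clipped Voronoi polygon meets the sampling-window border;
        ``hull_peel`` drops convex-hull cells.
    sd_convention : {"sample", "population"}
        Standard-deviation convention (n-1 vs n) used inside the
        coefficient of clustering.
    cc_neighbors : {"all", "interior_only"}
        Whether boundary-flagged cells may appear in the neighbourhoods
        that form the local coefficient of variation.
    min_interior : int
        Minimum number of retained cells required for CC.

    Attributes
    ----------
    n_total_ : int
        Number of cells in the field.
    n_interior_ : int
        Cells retained after boundary exclusion.
    density_ : float
        Cells per mm^2 of sampling window (all cells counted).
    areas_ : (n,) ndarray
        Clipped Voronoi-domain area of every cell, um^2.
    areas_interior_ : ndarray
        Areas of retained cells only — the histogram input.
    interior_ : (n,) ndarray of bool
        Retention mask.
    neighbors_ : list of ndarray
        Voronoi adjacency (indices), per cell.
    skewness_g1_ : float
        g1 skewness of the retained area distribution.
    cc_ : float
        Coefficient of clustering.
    window_ : tuple
        Sampling window used, (x_min, y_min, x_max, y_max) in um.

    Examples
    --------
    >>> import numpy as np
    >>> from conemosaic import MosaicAnalyzer
    >>> rng = np.random.default_rng(0)
    >>> pts = rng.uniform(0, 1000, size=(500, 2))
    >>> an = MosaicAnalyzer().fit(pts, window=(0, 0, 1000, 1000))
    >>> round(an.density_)
    500
    """

    def __init__(
        self,
        edge_rule: str = "window_touch",
        sd_convention: str = "sample",
        cc_neighbors: str = "all",
        min_interior: int = 10,
    ):
        self.edge_rule = edge_rule
        self.sd_convention = sd_convention
        self.cc_neighbors = cc_neighbors
        self.min_interior = min_interior

    def fit(self, X, y=None, *, window=None):
        """Analyze one field.

        Parameters
        ----------
        X : (n, 2) array-like or PointField
            Cell positions in micrometres.
        y : ignored
            Present for estimator-API compatibility.
        window : tuple, optional
            Sampling rectangle; defaults to the field's own window (for a
            PointField) or the whole-micrometre bounding box of X.
        """
        if isinstance(X, PointField):
            field = X.with_window(window) if window is not None else X
        else:
            pts = np.asarray(X, dtype=float)
            if window is None:
                from .io_coords import _bounding_window

                window = _bounding_window(pts)
            field = PointField(pts, window)
        self.field_ = field
        self.window_ = field.window
        vr = compute_voronoi(field)
        interior_mask(vr, field, rule=self.edge_rule)
        self.voronoi_ = vr
        self.n_total_ = field.n
        self.n_interior_ = vr.n_interior
        self.density_ = density(field)
        self.areas_ = vr.areas
        self.interior_ = vr.interior
        self.neighbors_ = vr.neighbors
        self.areas_interior_ = vr.areas[vr.interior]
        self.skewness_g1_ = skewness_g1(self.areas_interior_)
        self.cc_ = coefficient_of_clustering(
            vr,
            sd_convention=self.sd_convention,
            cc_neighbors=self.cc_neighbors,
            min_cells=self.min_interior,
        )
        return self

    def summary(self) -> MosaicStatistics:
        """Fitted summaries bundled as a :class:`MosaicStatistics`."""
        return MosaicStatistics(
            n_total=self.n_total_,
            n_interior=self.n_interior_,
            density=self.density_,
            areas_interior=self.areas_interior_,
            skewness_g1=self.skewness_g1_,
            cc=self.cc_,
        )
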