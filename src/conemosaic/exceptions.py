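"""Exception hierarchy for conemosaic."""


class ConemosaicError(Exception):
    """Base class for all conemosaic errors."""


class CoordinateParseError(ConemosaicError):
    """A coordinate table contains cells that cannot be read as numbers."""


class InsufficientPointsError(ConemosaicError):
    """Fewer points than the operation requires (Voronoi needs >= 4)."""


class DegenerateGeometryError(ConemosaicError):
    """Point configuration admits no 2-D tessellation (e.g. all collinear)."""


class InsufficientInteriorCellsError(ConemosaicError):
    """Too few cells survive boundary exclusion for the statistic."""


class ZeroVarianceError(ConemosaicError):
    """A scale-free statistic is undefined because the sample has no spread."""


class ClusteringUndefinedError(ConemosaicError):
    """No cell retains a usable neighborhood, so CC cannot be formed."""


class NoDotsDetectedError(ConemosaicError):
    """Dot-annotation image yields no connected components above threshold."""


class PackingFailureError(ConemosaicError):
    """Hard-core sampling could not reach the target count.

    The message names the binding constraint (spacing, rim geometry or
    hole-centre separation).
    """
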