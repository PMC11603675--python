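"""Package-level exception types."""


class PalatemapError(Exception):
    """Base class for all package errors."""


class GeometryError(PalatemapError):
    """Degenerate or inconsistent geometric input (collinear landmarks, ...)."""


class PlacementError(PalatemapError):
    """A probe point could not be projected onto the oral surface."""


class ResolutionError(PalatemapError):
    """Voxel spacing too coarse to resolve the requested structure."""


class DesignError(PalatemapError):
    """Rank-deficient or otherwise unusable statistical design."""


class InsufficientDataError(PalatemapError):
    """Too few observations for the requested statistic."""


class StageError(PalatemapError):
    """A pipeline stage failed; the message names the stage."""
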