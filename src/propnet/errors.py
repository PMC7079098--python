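"""Exception hierarchy.

Every contract violation in the package raises a subclass of
:class:`PropnetError`, so callers can catch the package's failures without
masking genuine bugs (which surface as ordinary Python exceptions).
"""


class PropnetError(Exception):
    """Base class for all propnet errors."""


class FormatError(PropnetError):
    """Unreadable file or unsupported volume format/extension."""


class DimensionalityError(PropnetError):
    """Volume payload is not three-dimensional."""


class GeometryError(PropnetError):
    """Inconsistent grids, out-of-range windows, or invalid polygons."""


class RoiError(PropnetError):
    """Empty or unusable region of interest."""


class MaskTypeError(PropnetError):
    """An operation received a mask where an image was required, or vice versa."""


class ShapeError(PropnetError):
    """Grid-shape mismatch between operands."""


class LatticeError(PropnetError):
    """Invalid B-spline control lattice."""


class RegionError(PropnetError):
    """Empty region passed to a region statistic."""


class MetricError(PropnetError):
    """Metric undefined for the given inputs (e.g. empty mask)."""


class SpecError(PropnetError):
    """Invalid phantom or run specification."""


class ConfigError(PropnetError):
    """Invalid run configuration."""


class InputError(PropnetError):
    """Network input violates the preprocessing contract."""


class TrainingDivergenceError(PropnetError):
    """Training loss became non-finite; carries the last finite state."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


class SplitError(PropnetError):
    """Too few patients for the requested cross-validation split."""
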