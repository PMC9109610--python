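"""Exception hierarchy.

Every contract violation in the package raises a subclass of VentimapError so
callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class VentimapError(Exception):
    """Base class for all ventimap errors."""


class FormatError(VentimapError):
    """A file or array does not have the expected structure (e.g. a 4-D image
    where a 3-D volume is required)."""


class GeometryError(VentimapError):
    """Shapes, spacings, origins or physical extents are incompatible."""


class ParameterError(VentimapError):
    """A parameter is outside its documented domain."""


class SegmentationError(VentimapError):
    """Lung segmentation produced an empty or degenerate mask."""


class DataError(VentimapError):
    """Input data violates a statistical or physical precondition (e.g. too
    many guarded voxels in the density-change estimator)."""


class SplitError(VentimapError):
    """A train/validation/test split cannot be formed from the given subjects."""


class UndefinedStatisticError(VentimapError):
    """A statistic is undefined for the given input (e.g. Spearman correlation
    of a constant signal)."""


class ConfigError(VentimapError):
    """A model or run configuration is internally inconsistent."""
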