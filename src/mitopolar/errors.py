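"""Exception hierarchy used across the package."""


class MitopolarError(Exception):
    """Base class for package errors."""


class ConfigurationError(MitopolarError, ValueError):
    """Invalid generator or pipeline configuration."""


class GenerationError(MitopolarError, ValueError):
    """Synthetic data could not be generated from a valid configuration."""


class GeometryError(MitopolarError, ValueError):
    """Degenerate or invalid geometry (zero area, coincident points...)."""


class BoundsError(MitopolarError, ValueError):
    """A contour or sampling transect leaves the image raster."""


class LabelingError(MitopolarError, ValueError):
    """A required side/phase label is missing or inconsistent."""


class NormalizationError(MitopolarError, ValueError):
    """Cytoplasmic reference intensity is non-positive."""


class ConsistencyError(MitopolarError, ValueError):
    """Profiles on mixed grids or normalization states cannot be combined."""


class DetectionError(MitopolarError, ValueError):
    """Spindle pole detection failed (fewer than two maxima)."""


class RangeError(MitopolarError, ValueError):
    """An angle lies outside its declared range."""


class InputError(MitopolarError, ValueError):
    """Malformed or insufficient input to an operation."""


class ParseError(MitopolarError, ValueError):
    """A file could not be parsed; the message names the offending field."""
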