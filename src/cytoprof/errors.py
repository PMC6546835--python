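"""Exception hierarchy for cytoprof.

Every error raised by the package derives from :class:`CytoprofError`, so
callers (and the CLI) can distinguish user/input problems from genuine bugs.
"""


class CytoprofError(Exception):
    """Base class for all package errors."""


class ConfigError(CytoprofError):
    """A parameter or configuration value is outside its documented domain."""


class PlacementError(CytoprofError):
    """Non-overlapping cell placement failed (requested density too high)."""


class FormatError(CytoprofError):
    """An input file is not in a supported image format / layout."""


class EmptyInputError(CytoprofError):
    """An operation received an empty image, mask or collection."""


class GeometryError(CytoprofError):
    """Shapes or coordinate frames of inputs are inconsistent."""


class CalibrationError(CytoprofError):
    """Single-cell area calibration is missing, empty or non-positive."""


class UndefinedStatisticError(CytoprofError):
    """A statistic is undefined for the given inputs (e.g. no target area)."""


class EventOrderError(CytoprofError):
    """Kill-event timestamps are out of order (dead-stain before contact)."""


class SampleSizeError(CytoprofError):
    """A statistical comparison was requested with too few samples."""
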