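"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 1 (usage / configuration problems),
``DataError`` and its subclasses map to exit code 2 (problems with the data
itself).
"""


class IvpharmError(Exception):
    """Base class for all package errors."""


class ConfigError(IvpharmError):
    """Invalid parameter, configuration file, or CLI usage."""


class DataError(IvpharmError):
    """The input data cannot be processed as requested."""


class StructuralError(DataError):
    """Shapes, page counts, or identifiers do not line up."""


class DegenerateInputError(DataError):
    """An image is constant (or otherwise content-free) where content is required."""


class UndefinedMetricError(DataError):
    """A quality metric is undefined for the given reference (e.g. zero variance)."""


class CalibrationError(DataError):
    """The dilution table cannot support a calibration fit."""


class GenerationError(DataError):
    """The synthetic scene specification cannot be realised."""
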