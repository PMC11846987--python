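"""Exception hierarchy for the esokin pipeline.

Every error raised by the package derives from :class:`EsokinError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class EsokinError(Exception):
    """Base class for all package errors."""


class FormatError(EsokinError):
    """A recording file does not conform to the recording CSV dialect."""


class ParseError(EsokinError):
    """A cell in a recording file could not be parsed as a finite number."""


class RateError(EsokinError):
    """Sampling-rate metadata is inconsistent or time stamps are non-uniform."""


class UnitError(EsokinError):
    """An operation received a trace in the wrong units."""


class LengthError(EsokinError):
    """A trace is too short for the requested operation."""


class DegenerateInputError(EsokinError):
    """The input is degenerate for the operation (e.g. every sample flagged
    as an outlier, or a zero-variance group in a t test)."""


class DegenerateGeometryError(EsokinError):
    """Point cloud is collinear or otherwise too flat for an ellipse fit."""


class ConfigurationError(EsokinError):
    """A run was requested with an invalid or insufficient configuration."""
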