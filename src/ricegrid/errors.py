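"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation/config errors -> 2,
I/O errors -> 3, degenerate geometry -> 4.
"""


class RiceGridError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RiceGridError, ValueError):
    """Input data violates a precondition (wrong dtype, empty sample, ...)."""


class InvalidParameterError(RiceGridError, ValueError):
    """A parameter value is outside its allowed range."""


class DegenerateGeometryError(RiceGridError):
    """Geometry too degenerate to process (collinear points, < 3 sites, ...)."""


class UndefinedMetricError(RiceGridError):
    """A score's denominator is zero; the message names the metric."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric '{metric}' is undefined (zero denominator)")


class InsufficientDataError(RiceGridError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateDataError(RiceGridError, ValueError):
    """Data admits no proper estimate (e.g. zero-variance sample for a gamma fit)."""


class UnitMismatchError(RiceGridError, ValueError):
    """Two point sets are expressed in different units."""


class ConfigError(RiceGridError, ValueError):
    """Configuration file failed validation."""


class ParseError(RiceGridError, ValueError):
    """A text table could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
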