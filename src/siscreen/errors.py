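"""Exception hierarchy.

Validation errors (bad input data, broken contracts) are distinguished from
runtime errors so the CLI can map them to distinct exit codes.
"""


class SiscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(SiscreenError):
    """Malformed or contract-violating input data."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedStatisticError(SiscreenError):
    """A statistic is mathematically undefined for the given input
    (e.g. z'-factor with coincident control means, viability per cell
    at zero count)."""
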