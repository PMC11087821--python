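"""Exception and warning types shared across the package."""


class DraphnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DraphnetError, ValueError):
    """An argument violates a documented precondition."""


class MatrixParseError(DraphnetError, ValueError):
    """A delimited-text matrix file failed validation; the message names the row."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped at its iteration cap."""
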