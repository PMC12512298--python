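"""Shared exception types."""


class AnoleChromaError(Exception):
    """Base class for package errors."""


class InvalidInputError(AnoleChromaError, ValueError):
    """Input violates a precondition."""


class DegenerateInputError(AnoleChromaError, ValueError):
    """Input is formally valid but leads to a degenerate computation."""


class ConvergenceError(AnoleChromaError, RuntimeError):
    """A fit failed to converge (e.g. complete separation)."""


class InvalidComparisonError(AnoleChromaError, ValueError):
    """Model fits being compared were not produced from the same records."""
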