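"""Typed errors raised by psychnet.

Every validation failure raises one of these; malformed input is never
silently coerced.
"""


class PsychnetError(Exception):
    """Base class for all psychnet errors."""


class SpecError(PsychnetError, ValueError):
    """A variable specification or generator/study config is invalid."""


class DataValidationError(PsychnetError, ValueError):
    """A data table violates its variable specification."""


class EstimationError(PsychnetError, RuntimeError):
    """A nodewise fit failed (non-convergence, separation, degenerate input)."""
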