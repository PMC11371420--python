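"""Exception hierarchy.

All package errors derive from :class:`ConesectError` so callers (and the
CLI) can distinguish contract violations from programming errors.
"""


class ConesectError(Exception):
    """Base class for all errors raised by this package."""


class AxisError(ConesectError):
    """Wavelength axes are incompatible (mismatch, insufficient overlap)."""


class RangeError(AxisError):
    """A requested wavelength range extends beyond the available data."""


class UsageError(ConesectError):
    """Arguments violate an operation's contract (e.g. bad observer pairing)."""


class DegeneracyError(ConesectError):
    """The intersection problem does not have a unique one-dimensional
    solution (e.g. duplicated observers give a null space of dimension > 1)."""


class ConvergenceError(ConesectError):
    """An iterative solver failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConstructionError(ConesectError):
    """A synthetic construction failed its verification (e.g. rank check)."""
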