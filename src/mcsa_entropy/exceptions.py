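"""Exception hierarchy.

All package errors derive from :class:`McsaError` so callers can catch one
type; subclasses distinguish user-parameter problems from numerical
failures and malformed inputs.
"""


class McsaError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(McsaError, ValueError):
    """An argument or configuration value is invalid."""


class FormatError(McsaError, ValueError):
    """An input file could not be parsed under its declared format."""


class InsufficientDataError(McsaError, ValueError):
    """The input holds too few frames/samples for the requested operation."""


class SuperpositionError(McsaError, RuntimeError):
    """Least-squares superposition failed (degenerate reference geometry)."""


class EstimationError(McsaError, RuntimeError):
    """A density/entropy estimate could not be computed on this data."""


class OracleError(McsaError, ValueError):
    """No reference-entropy oracle is available for the requested spec."""


class DegenerateEnsembleError(McsaError, RuntimeError):
    """All covariance eigenvalues fell below the floor."""
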