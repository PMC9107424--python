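"""Exception hierarchy.

All errors raised by this package derive from :class:`RegGNNError` so callers
can catch them with a single clause; the concrete subclasses also derive from
the closest builtin (``ValueError`` / ``ArithmeticError``) so that generic
numeric code keeps working.
"""


class RegGNNError(Exception):
    """Base class for all errors raised by reggnn."""


class ValidationError(RegGNNError, ValueError):
    """An input violates a structural invariant (shape, symmetry, range)."""


class DegenerateInputError(RegGNNError, ValueError):
    """An input is structurally valid but numerically unusable (e.g. a
    correlation matrix that stays singular after regularization, or an
    all-zero graph)."""


class ConfigurationError(RegGNNError, ValueError):
    """A configuration value is inconsistent with the data it is applied to."""


class ConvergenceError(RegGNNError, ArithmeticError):
    """An iterative solver did not converge within its iteration budget."""


class DivergenceError(RegGNNError, ArithmeticError):
    """Training produced a non-finite loss."""
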