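"""Exception hierarchy for dcemix.

All package errors derive from :class:`DcemixError` so callers can catch the
package's failures with a single except clause while still discriminating
between design, estimation and data problems.
"""


class DcemixError(Exception):
    """Base class for all dcemix errors."""


class InvalidSpecificationError(DcemixError):
    """A factor, population or model specification violates its invariants."""


class SingularDesignError(DcemixError):
    """The design's information matrix is singular (an attribute carries no
    information, e.g. constant across all alternatives and tasks)."""


class UnderIdentifiedDesignError(DcemixError):
    """Fewer choice tasks than model coefficients were requested."""


class DominanceConstructionError(DcemixError):
    """A dominance task cannot be built (no factor has a preference direction)."""


class IdentificationError(DcemixError):
    """A model coefficient is not identified by the data (its attribute never
    varies between the alternatives of any task)."""


class ConvergenceError(DcemixError):
    """The optimizer failed in a way that invalidates the result entirely.

    Plain non-convergence is *not* raised — it is flagged on the result."""


class MissingValidityTaskError(DcemixError):
    """A block lacks the dominance or repeat task a validity check needs."""


class PairingError(DcemixError):
    """A repeat-role task cannot be paired with its original."""


class InsufficientSampleError(DcemixError):
    """An exclusion rule leaves fewer respondents than the configured minimum."""


class DegenerateModelError(DcemixError):
    """All coefficients are zero; relative importance is undefined."""


class UndefinedTradeoffError(DcemixError):
    """The denominator coefficient of a marginal rate of substitution is zero."""


class ConfigurationError(DcemixError):
    """A run configuration or factor grouping is incomplete or inconsistent."""


class DataValidationError(DcemixError):
    """A choice-data table violates the long-format contract."""


class NumericUnderflowError(DcemixError):
    """All simulated probabilities underflowed; increase the draw count."""
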