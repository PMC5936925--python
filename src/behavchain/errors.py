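"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`BehavchainError` so that callers
(CLI, pipeline driver) can attach the stage name and offending record
without string-matching on messages.
"""


class BehavchainError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BehavchainError):
    """A simulation or pipeline configuration field is invalid."""


class ValidationError(BehavchainError):
    """An input record violates the data model (bad label, bad shape)."""


class ResolutionError(BehavchainError):
    """A required lookup (e.g. sunrise/sunset for a site-date) is missing."""


class OutOfRangeError(BehavchainError):
    """A time or proportion falls outside its documented domain."""


class StandardizationError(BehavchainError):
    """Scan spacing cannot be mapped onto the requested regular grid."""


class DegeneracyError(BehavchainError):
    """A transition matrix has no unique stationary distribution."""


class EstimationError(BehavchainError):
    """A transition matrix row has no supporting observations."""


class AggregationError(BehavchainError):
    """Records from incompatible groups (e.g. mixed dates) were combined."""


class UndefinedExposureError(BehavchainError):
    """Exposure requested for a time category with zero samples."""


class ConvergenceError(BehavchainError):
    """Iterative fitting failed to converge within the iteration cap."""


class SelectionError(BehavchainError):
    """Model selection was attempted with no converged fits."""


class PairingError(BehavchainError):
    """A control/pressure comparison is missing one of its two sides."""


class DegenerateTestError(BehavchainError):
    """A test statistic is undefined (e.g. pooled proportion 0 or 1)."""
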