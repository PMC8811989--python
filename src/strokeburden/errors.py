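"""Exception hierarchy shared by every module."""


class StrokeBurdenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StrokeBurdenError):
    """A configuration file is missing, unparseable or lacks a required key."""


class ValidationError(StrokeBurdenError, ValueError):
    """A loaded or sampled value violates a model invariant."""


class DomainError(StrokeBurdenError, ValueError):
    """An argument lies outside the domain of an operation."""


class CalibrationError(StrokeBurdenError, RuntimeError):
    """Life-table calibration failed to reach the required tolerance."""


class StateError(StrokeBurdenError, RuntimeError):
    """An operation was invoked before its prerequisite stage ran."""
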