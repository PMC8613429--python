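"""Exception types shared across the pipeline."""


class TypetrailError(Exception):
    """Base class for all package errors."""


class DataValidationError(TypetrailError):
    """Input data violates a documented precondition (unsorted, duplicated, mismatched)."""


class ConfigurationError(TypetrailError):
    """A configuration value is invalid; the message names the offending field."""


class InsufficientDataError(TypetrailError):
    """Too few observations for the requested statistic."""


class SingularDesignError(TypetrailError):
    """Fixed-effect design matrix is rank deficient; message lists collinear columns."""


class NumericError(TypetrailError):
    """A numeric routine received parameters outside its valid domain."""
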