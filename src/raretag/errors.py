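"""Typed errors raised across the package."""


class RaretagError(Exception):
    """Base class for package errors."""


class ConfigurationError(RaretagError):
    """Invalid thresholds, sizes or option combinations."""


class DataValidationError(RaretagError):
    """Input data violates a structural invariant."""


class ConstantVectorError(RaretagError):
    """Correlation requested on a constant (monomorphic) vector."""


class DegenerateModelError(RaretagError):
    """Regression model with non-positive residual degrees of freedom."""
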