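"""Shared exception types."""


class MyotaskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MyotaskError, ValueError):
    """Malformed or inconsistent input."""


class DegenerateInputError(MyotaskError, ValueError):
    """Input is formally valid but statistically degenerate (constant
    samples, singular covariance, undersized class)."""
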