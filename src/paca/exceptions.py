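"""Exception hierarchy used across the package."""


class PacaError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PacaError, ValueError):
    """Invalid input data or configuration."""


class RegimeError(PacaError, ValueError):
    """The requested solver is inapplicable in this n/m regime.

    Raised with an advisory message: sample-space CCA requires more features
    than samples in either group, so wide data (n >= m) must go through the
    randomized estimator and vice versa.
    """


class ModelArchiveError(PacaError, OSError):
    """A model archive is unreadable, truncated, or of an unsupported version."""
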