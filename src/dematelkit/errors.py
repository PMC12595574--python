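"""Exception types shared across the package."""


class DematelkitError(Exception):
    """Base class for all package errors."""


class ValidationError(DematelkitError, ValueError):
    """Invalid input data: shape, range, diagonal, or label problems."""


class ComputationError(DematelkitError, RuntimeError):
    """A numerical stage could not produce a meaningful result."""
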