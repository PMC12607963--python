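"""Exception types shared across the package."""


class SgsimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SgsimError):
    """Non-finite or mis-shaped numerical input."""


class ConfigurationError(SgsimError):
    """A run configuration that is inconsistent or unphysical."""


class DomainError(SgsimError):
    """A parameter outside the mathematical domain of a formula."""
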