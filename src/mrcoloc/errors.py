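"""Exception hierarchy shared across the package."""


class MrColocError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MrColocError):
    """A user-supplied configuration (column map, config file, preset) is invalid."""


class EmptySetError(MrColocError):
    """An operation that requires at least one variant received none."""


class InsufficientInstrumentsError(MrColocError):
    """An estimator was called with fewer instruments than it requires."""


class DomainError(MrColocError, ValueError):
    """A numeric argument is outside the domain of the requested computation."""
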