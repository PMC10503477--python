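"""Exception hierarchy shared across the package."""


class PigaitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PigaitError):
    """A configuration value is structurally invalid (counts, noise scales...)."""


class DomainError(PigaitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class IntegrityError(PigaitError):
    """Input data violate an internal consistency requirement."""
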