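"""Exception types shared across the package."""


class BcsimError(Exception):
    """Base class for package errors."""


class ParameterDomainError(BcsimError, ValueError):
    """A distribution or config parameter violates its domain constraint."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class InsufficientDataError(BcsimError, ValueError):
    """Too few observations for the requested estimate."""


class IntegrityError(BcsimError, ValueError):
    """Structurally invalid input (overlapping tasks, missing events, ...)."""


class ConfigError(BcsimError, ValueError):
    """Invalid or unparseable simulation configuration."""
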