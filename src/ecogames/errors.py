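"""Exception types shared across the package."""


class EcoGamesError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EcoGamesError, ValueError):
    """A state or parameter lies outside its admissible domain."""


class DegenerateSystemError(EcoGamesError):
    """The strategy dynamics vanish identically on the environmental
    nullcline, so the fixed-point set is a continuum rather than a finite
    list of equilibria."""


class IntegrationError(EcoGamesError):
    """The ODE solver failed.  ``partial`` carries whatever trajectory was
    produced before the failure (may be ``None``)."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class ConfigError(EcoGamesError, ValueError):
    """A run configuration failed schema validation."""
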