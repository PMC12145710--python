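"""Exception hierarchy shared across the package."""


class ViscogelError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ViscogelError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateModelError(ViscogelError, ValueError):
    """Model parameters make the requested quantity undefined (e.g. eta_eff = 0 with E1 > 0)."""


class InsufficientDataError(ViscogelError, ValueError):
    """Not enough samples to perform the requested computation."""


class IdentifiabilityError(ViscogelError, ValueError):
    """The requested parameters cannot be identified from the supplied data."""


class FitError(ViscogelError, RuntimeError):
    """Non-linear least squares failed to converge."""


class SolverError(ViscogelError, RuntimeError):
    """The ODE integrator failed; carries solver diagnostics in the message."""


class ConfigError(ViscogelError, ValueError):
    """Invalid or inconsistent run configuration."""


class ParseError(ViscogelError, ValueError):
    """A data file does not conform to the documented dialect."""


class UndefinedRatioError(ViscogelError, ZeroDivisionError):
    """A ratio is undefined because its denominator signal is zero."""
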