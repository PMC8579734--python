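"""Exception hierarchy shared across the package."""


class IvimKurtError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IvimKurtError, ValueError):
    """An input object violates a documented invariant."""


class DomainError(IvimKurtError, ValueError):
    """A scalar argument is outside its mathematical domain (e.g. b < 0)."""


class ConfigurationError(IvimKurtError, ValueError):
    """A required configuration element is missing or inconsistent
    (e.g. the acquisition scheme lacks a b-value the operation needs)."""


class InsufficientDataError(IvimKurtError, ValueError):
    """Too few observations for the requested statistic."""


class PlacementError(IvimKurtError, RuntimeError):
    """Lesion placement in the synthetic volume failed after bounded retries."""


class SeparationWarning(UserWarning):
    """Logistic-regression classes are perfectly separated; coefficients are
    driven to the iteration cap but fitted probabilities still rank correctly."""
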