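"""Exception hierarchy shared across the package."""


class PainbalanceError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PainbalanceError, ValueError):
    """Input violates a documented contract (range, length, design)."""


class ConfigurationError(PainbalanceError, ValueError):
    """A configuration object is internally inconsistent."""


class GenerationError(PainbalanceError, RuntimeError):
    """A stochastic generator failed after bounded retries."""


class DegenerateFitError(PainbalanceError, RuntimeError):
    """Data admit no meaningful fit (e.g. all ratings identical)."""


class DegenerateSubjectError(PainbalanceError, RuntimeError):
    """A subject cannot contribute to a model (constant variable, too few trials)."""


class DegenerateModeratorError(PainbalanceError, RuntimeError):
    """A second-level moderator is constant after residualization."""


class CollinearityError(PainbalanceError, RuntimeError):
    """Design matrix is rank-deficient for the requested regression."""


class MissingConditionError(PainbalanceError, ValueError):
    """A required design cell has no trials."""


class EmptyModelError(PainbalanceError, ValueError):
    """A trial filter removed every row."""
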