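"""Exception hierarchy shared across the package."""


class PMSurfaceError(Exception):
    """Base class for all pmsurface errors."""


class SchemaError(PMSurfaceError):
    """A required column or field is missing or malformed."""


class ValidationError(PMSurfaceError):
    """Input data violate a hard structural invariant (e.g. duplicate coordinates)."""


class DomainError(PMSurfaceError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FitError(PMSurfaceError):
    """An iterative fit failed to converge.

    Carries ``best_so_far`` (the best parameter set reached) and ``diagnostics``
    so callers can inspect the failure.
    """

    def __init__(self, message, best_so_far=None, diagnostics=None):
        super().__init__(message)
        self.best_so_far = best_so_far
        self.diagnostics = diagnostics or {}


class SingularSystemError(PMSurfaceError):
    """A linear system arising from interpolation is singular."""
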