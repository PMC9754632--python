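"""Exception hierarchy for spheromech."""


class SpheromechError(Exception):
    """Base class for all package-specific errors."""


class InvalidContextError(SpheromechError, ValueError):
    """Magnetization context with non-positive Mv or grad(B)."""


class IntegrationError(SpheromechError, RuntimeError):
    """Profile integration failed to terminate or resolve the apex."""


class FitConvergenceError(SpheromechError, RuntimeError):
    """An optimizer failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class OutOfMeasurableRangeError(SpheromechError, ValueError):
    """Landmarks describe an undeformed sphere: surface tension is unbounded."""


class DegenerateModelError(SpheromechError, ValueError):
    """Model is degenerate for the requested inputs (e.g. HillSlope = 0)."""


class DegenerateFitError(SpheromechError, ValueError):
    """Geometry too degenerate to fit (e.g. collinear points for a circle)."""


class UnidentifiableError(SpheromechError, ValueError):
    """Data carry no information about the requested parameter."""
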