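"""Exception hierarchy for pbcharge."""


class PBChargeError(Exception):
    """Base class for all pbcharge errors."""


class InvalidParameterError(PBChargeError, ValueError):
    """A physical parameter is outside its admissible range."""


class GeometryError(PBChargeError, ValueError):
    """Requested geometry is degenerate or inconsistent."""


class SolverError(PBChargeError, RuntimeError):
    """Nonlinear solve failed to converge.

    Carries the residual-norm history so callers can diagnose divergence.
    """

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class NotFoundError(PBChargeError, ValueError):
    """A root / crossing (pI, half-ionization pH, ...) is not bracketed."""


class ConfigError(PBChargeError, ValueError):
    """Run configuration failed validation."""
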