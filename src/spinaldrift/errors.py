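"""Exception hierarchy for solver and validation failures."""


class SpinaldriftError(Exception):
    """Base class for all package errors."""


class InputError(SpinaldriftError, ValueError):
    """Invalid user input (malformed waveform, out-of-domain bolus, ...)."""


class ResolutionError(SpinaldriftError, ValueError):
    """A requested field cannot be resolved on the given grid."""


class StabilityError(SpinaldriftError, RuntimeError):
    """A time step violates the stability limit of an explicit scheme."""


class ConvergenceError(SpinaldriftError, RuntimeError):
    """An iterative procedure failed to converge.

    Carries the residual history so callers can diagnose the failure.
    """

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history) if history is not None else []


class ConservationError(SpinaldriftError, RuntimeError):
    """A conservation contract is violated (incompatible Poisson source,
    unprojected drift field fed to the reduced transport solver, ...)."""
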