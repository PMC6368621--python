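"""Exception types shared across the package."""


class CryopeelError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CryopeelError, ValueError):
    """A parameter violates its documented domain (non-positive stiffness, ...)."""


class FormatError(CryopeelError, ValueError):
    """A trace or config file violates the on-disk contract."""


class StepError(CryopeelError, RuntimeError):
    """Relaxation failed to converge at a retraction step.

    Carries the tip height and the residual gradient norm for diagnosis.
    """

    def __init__(self, z: float, residual: float, message: str | None = None):
        self.z = z
        self.residual = residual
        super().__init__(
            message
            or f"relaxation did not converge at Z={z:.4f} nm "
            f"(residual gradient {residual:.3e} nN)"
        )


class FitError(CryopeelError, RuntimeError):
    """Envelope fitting failed (degenerate assignment, inconsistent k_tip, ...)."""


class InsufficientEventsError(FitError):
    """Too few dips/peaks to compute statistics or fit the envelope."""
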