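"""Exception hierarchy for the SP-DRI toolkit."""


class SpdriError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(SpdriError, ValueError):
    """An argument or field violates a documented precondition."""


class FormatError(SpdriError, ValueError):
    """A file does not conform to the expected on-disk schema."""


class DegenerateProfileError(SpdriError, ValueError):
    """A profile carries no structure a fit could latch onto (e.g. constant)."""


class FitError(SpdriError, RuntimeError):
    """A least-squares fit failed to converge.

    Carries ``last_residual`` when the optimizer produced one before giving up.
    """

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual


class DetectionError(SpdriError, RuntimeError):
    """Deflection detection found no usable samples."""
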