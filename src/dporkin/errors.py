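"""Exception hierarchy for dporkin.

All failures raised by the library derive from :class:`DporkinError` so
callers (and the CLI) can distinguish library errors from programming
errors.
"""


class DporkinError(Exception):
    """Base class for all dporkin errors."""


class InvalidInputError(DporkinError, ValueError):
    """Raised when an input violates a documented precondition."""


class CalibrationError(DporkinError):
    """Raised when reference calibration fails or yields an implausible
    scale factor (signals inconsistent reference spectra)."""


class FitFailureError(DporkinError):
    """Raised when a kinetic fit cannot converge or the data are
    degenerate (e.g. a constant trace has no identifiable rate)."""


class IntegratorError(DporkinError):
    """Raised when the ODE integrator fails; carries solver diagnostics."""
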