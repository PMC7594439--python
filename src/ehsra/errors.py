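"""Exception and warning hierarchy shared by all ehsra modules."""


class EhsraError(Exception):
    """Base class for all package errors."""


class InputError(EhsraError, ValueError):
    """Invalid user input: malformed files, missing columns, bad values."""


class CalibrationError(EhsraError, ValueError):
    """Calibration produced an unusable result (e.g. non-monotone cut-points)."""


class NumericalError(EhsraError, RuntimeError):
    """A numerical routine failed (non-PD matrix, non-convergence, ...)."""


class CalibrationWarning(UserWarning):
    """Input lies outside the range the index was calibrated on."""
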