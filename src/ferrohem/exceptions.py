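"""Exception hierarchy.

``ValidationError`` (and subclasses) means the *input* was unusable and maps
to CLI exit code 1; ``FitError`` means an optimisation failed and maps to
exit code 2.
"""


class FerrohemError(Exception):
    """Base class for all package errors."""


class ValidationError(FerrohemError, ValueError):
    """Invalid or inconsistent input data or parameters."""


class GridError(ValidationError):
    """Wavelength / time grids do not match and cannot be reconciled."""


class DegenerateDataError(ValidationError):
    """Data carry no usable signal (e.g. a flat time series)."""


class NoStructureError(ValidationError):
    """A surface profile has no resolvable periodic structure."""


class UndefinedValueError(ValidationError):
    """A requested statistic is undefined (zero total, zero variance)."""


class FitError(FerrohemError, RuntimeError):
    """An iterative fit failed to converge.

    Parameters
    ----------
    message : str
    residuals : array-like, optional
        Residual vector (or final residual norm) at the point of failure,
        kept so callers can diagnose the failure.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals
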