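"""Exception hierarchy shared across the package."""


class MibgkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MibgkitError):
    """Inconsistent or unknown configuration (organ names, grids, parameters)."""


class ValidationError(MibgkitError, ValueError):
    """Input data violate a documented precondition."""


class CalibrationError(MibgkitError):
    """The inverse problem of matching H/M targets has no solution.

    Carries the per-target residuals so the caller can see how far off
    the best attempt was.
    """

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class RoiPlacementError(MibgkitError):
    """Automatic ROI placement failed; a manual ROI is required."""


class FormatError(MibgkitError):
    """A file could not be parsed, or a required metadata field is missing."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class StageError(MibgkitError):
    """A pipeline stage failed; the message names the stage and its input."""


class ModelFitError(MibgkitError):
    """Statistical model estimation did not converge; carries diagnostics."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []
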