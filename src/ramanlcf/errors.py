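"""Exception hierarchy.

Everything raised on bad scientific input derives from :class:`RamanLCFError`
so callers (and the CLI) can distinguish domain failures from programming
errors.
"""


class RamanLCFError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RamanLCFError, ValueError):
    """A physical parameter is out of its admissible range (e.g. FWHM <= 0)."""


class GridError(RamanLCFError, ValueError):
    """Wavenumber-grid mismatch or out-of-range resampling request."""


class EmptyWindowError(RamanLCFError, ValueError):
    """A clip/analysis window selects no grid points."""


class NormalizationError(RamanLCFError, ValueError):
    """Reference band absent or non-positive in the normalization window."""


class RatioError(RamanLCFError, ValueError):
    """Band-ratio denominator window has non-positive maximum."""


class ConvergenceError(RamanLCFError, RuntimeError):
    """The NNLS active-set iteration exceeded its cap.

    Carries the iteration cap and the residual norm at abort.
    """

    def __init__(self, message: str, iterations: int, residual_norm: float):
        super().__init__(message)
        self.iterations = iterations
        self.residual_norm = residual_norm


class ParseError(RamanLCFError, ValueError):
    """Malformed row in a delimited text file; message names the line."""


class FormatError(RamanLCFError, ValueError):
    """Structurally invalid file (missing header, duplicate rows, ...)."""


class ConfigError(RamanLCFError, ValueError):
    """Run configuration failed validation (unknown or ill-typed keys)."""


class PipelineError(RamanLCFError, RuntimeError):
    """A pipeline stage failed; message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
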