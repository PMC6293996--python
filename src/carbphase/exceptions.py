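"""Exception hierarchy shared across the package."""


class CarbPhaseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CarbPhaseError):
    """A spectrum file could not be parsed; the message names the first bad line."""


class InsufficientDataError(CarbPhaseError):
    """Too few data points to proceed."""


class DomainError(CarbPhaseError, ValueError):
    """An operation was asked to work outside the data's spectral span."""


class GridError(CarbPhaseError):
    """Grids are irregular or misaligned where a regular/shared grid is required."""


class FitError(CarbPhaseError):
    """A least-squares peak fit failed to converge."""

    def __init__(self, message, init_center=None, window=None):
        super().__init__(message)
        self.init_center = init_center
        self.window = window


class CoverageError(CarbPhaseError):
    """The spectrum does not cover the spectral windows the analysis needs."""

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class ConfigError(CarbPhaseError):
    """Invalid configuration (unknown phase, empty template list, ...)."""
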