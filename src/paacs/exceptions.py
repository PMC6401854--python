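"""Exception hierarchy shared across the package."""


class PaacsError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PaacsError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ConfigurationError(PaacsError):
    """Required metadata (concentration, path length, files) is missing or invalid."""


class InsufficientDataError(PaacsError):
    """Too few usable data points for the requested analysis."""


class AnalysisError(PaacsError):
    """A data-analysis step failed (e.g. an equivalence point could not be located)."""


class FitError(PaacsError):
    """Nonlinear fitting failed to converge or the data are degenerate."""
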