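"""Exception hierarchy shared across the package."""


class CombotransError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CombotransError, ValueError):
    """An argument is outside its documented domain."""


class FitError(CombotransError):
    """A curve fit could not be performed (degenerate input)."""


class MarginError(CombotransError):
    """A combination matrix lacks the zero-dose single-agent margins."""


class FormatError(CombotransError):
    """A file does not conform to the expected CSV/YAML dialect."""


class ConvergenceError(CombotransError):
    """An iterative solver failed to reach its convergence criterion."""


class PairingError(CombotransError):
    """PK profile lists cannot be paired index-by-index."""


class DependencyError(CombotransError):
    """A pipeline stage is missing an upstream artifact."""
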