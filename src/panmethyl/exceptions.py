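"""Exception types shared across the package."""


class PanmethylError(Exception):
    """Base class for all package-specific errors."""


class DataError(PanmethylError):
    """Malformed or out-of-contract input data (bad values, duplicate ids, empty results)."""


class ConfigurationError(PanmethylError):
    """Invalid simulation or pipeline configuration."""


class ConvergenceError(PanmethylError):
    """An iterative procedure failed to reach its tolerance within the iteration cap."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
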