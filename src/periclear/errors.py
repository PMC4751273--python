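"""Exception hierarchy shared across the package."""


class PericlearError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PericlearError, ValueError):
    """A physical parameter violates its domain (sign, range, units)."""


class GeometryError(PericlearError, ValueError):
    """A synthetic geometry specification cannot be rasterized consistently."""


class SolverDivergenceError(PericlearError, RuntimeError):
    """The explicit time integration produced non-finite or runaway values."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class ConfigError(PericlearError, ValueError):
    """A run configuration failed validation before any compute started."""
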