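"""Exception types shared across the pipeline stages."""


class LidarHabError(Exception):
    """Base class for all package errors."""


class ConfigError(LidarHabError):
    """Invalid landscape, telemetry or pipeline configuration."""


class PointCloudParseError(LidarHabError):
    """Malformed point-cloud file; the message names the offending record."""


class NormalizationError(LidarHabError):
    """Height normalization impossible (no ground points in the plot)."""


class SimulationError(LidarHabError):
    """Telemetry simulation cannot proceed (e.g. zero intensity everywhere)."""


class ConvergenceError(LidarHabError):
    """Model fit did not converge; carries the final gradient norm."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm
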