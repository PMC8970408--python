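"""Exception hierarchy for :mod:`pcnet`."""


class PCNetError(Exception):
    """Base class for all pcnet errors."""


class ConfigurationError(PCNetError, ValueError):
    """A model, layer, or run configuration is inconsistent."""


class NumericError(PCNetError, FloatingPointError):
    """Non-finite values were encountered where finite ones are required."""


class DivergenceError(PCNetError, RuntimeError):
    """Inference iterations blew up past the configured bound.

    Attributes
    ----------
    iteration : int
        The inference iteration at which divergence was detected.
    """

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class OracleCapError(PCNetError, ValueError):
    """The finite-difference oracle was asked to handle too many parameters."""
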