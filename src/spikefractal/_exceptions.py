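"""Exception hierarchy shared across the package."""


class SpikeFractalError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpikeFractalError, ValueError):
    """A parameter is outside its admissible range."""


class InsufficientDataError(SpikeFractalError, ValueError):
    """Too few spikes / intervals to compute the requested statistic."""


class DegenerateDataError(SpikeFractalError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class EmbeddingError(SpikeFractalError, RuntimeError):
    """Circulant embedding of the target autocovariance is not positive
    semi-definite, so exact fractional Gaussian noise synthesis fails."""
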