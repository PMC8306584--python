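"""Exception hierarchy for the ramancd package."""


class RamanCDError(Exception):
    """Base class for all package errors."""


class ConfigError(RamanCDError, ValueError):
    """Invalid configuration value (grid bounds, component counts, ...)."""


class FormatError(RamanCDError, ValueError):
    """A spectrum or manifest file failed to parse or validate."""


class WindowError(RamanCDError, ValueError):
    """A spectral window does not overlap the grid sufficiently."""


class DataError(RamanCDError, ValueError):
    """Input data are unusable (NaNs, empty arrays, degenerate inputs)."""


class NormalizationError(RamanCDError, ValueError):
    """The internal-standard band area is non-positive or non-finite."""
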