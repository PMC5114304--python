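"""Exception hierarchy used across the package."""


class MyelinMapError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MyelinMapError, ValueError):
    """An argument violates a documented precondition."""


class LayoutError(MyelinMapError):
    """An ROI layout cannot be realised on the given mesh."""


class DegenerateDistributionError(MyelinMapError):
    """A value distribution is too degenerate for the requested statistic."""


class FWHMEstimationError(MyelinMapError):
    """The half-maximum crossings of a density could not be bracketed."""


class EmptyRegionError(MyelinMapError):
    """An ROI contains no included vertices after masking."""


class DegenerateContrastError(MyelinMapError):
    """Pooled ROI/neighbor standard deviation is zero; CNR undefined."""


class ConfigError(MyelinMapError):
    """An experiment configuration fails schema validation."""


class SchemaError(MyelinMapError):
    """A file to be read is missing required fields or columns."""
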