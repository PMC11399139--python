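"""Exception hierarchy for the pipeline."""


class MptetError(Exception):
    """Base class for all package errors."""


class MetadataError(MptetError):
    """A required metadata key is missing or malformed."""


class GridError(MptetError):
    """Two rasters that must share a grid do not."""


class DomainError(MptetError):
    """A scalar or raster input is outside its physical domain."""


class EdgeFitError(MptetError):
    """The Ts-Fr scatter cannot support a dry/wet edge fit."""


class EmptySummaryError(MptetError):
    """A summary was requested over zero valid pixels."""


class UndefinedStatisticError(MptetError):
    """A validation statistic is undefined for the given series."""


class GenerationError(MptetError):
    """Synthetic-scene parameters violate their invariants."""


class ConfigError(MptetError):
    """A run configuration failed validation."""
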