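"""Exception types shared across the package."""

__all__ = [
    "MirtarnetError",
    "ParseError",
    "DesignError",
    "ConfigurationError",
    "DegenerateDataError",
    "GenerationError",
    "ConsistencyError",
]


class MirtarnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MirtarnetError):
    """A file could not be parsed; the message names the offending row/column."""


class DesignError(MirtarnetError):
    """The sample design does not support the requested operation (e.g. unpaired)."""


class ConfigurationError(MirtarnetError):
    """A configuration object violates its invariants."""


class DegenerateDataError(MirtarnetError):
    """Input data carry no usable signal (e.g. zero variance everywhere)."""


class GenerationError(MirtarnetError):
    """Synthetic-data generation failed (e.g. rejection sampling exhausted)."""


class ConsistencyError(MirtarnetError):
    """Cross-referenced objects disagree (e.g. edge endpoint missing from annotations)."""
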