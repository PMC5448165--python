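"""Exception hierarchy for erk-decode."""


class ErkDecodeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ErkDecodeError):
    """A table or file violates the expected layout."""


class TableParseError(FormatError):
    """A cell could not be parsed; message names the offending location."""


class ConfigError(ErkDecodeError):
    """Inconsistent configuration (e.g. class ranges violating thresholds)."""


class InsufficientReplicationError(ErkDecodeError):
    """Too few replicates to build the empirical null."""


class DegenerateNullError(ErkDecodeError):
    """The variance model is zero somewhere; z-scores are undefined."""


class NormalizationError(ErkDecodeError):
    """Invalid normalization divisor (e.g. non-positive training mean)."""
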